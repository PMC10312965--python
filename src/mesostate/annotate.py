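"""Post-hoc naming of consensus states from an ROI parcellation.

Consensus state ids are arbitrary cluster indices; giving them
anatomical names (frontal, posterior, lateral, midline, hemispheric) is
annotation applied after clustering by comparing each consensus mean map
to an ROI parcellation — never part of the clustering itself. The
frontal-named states feed the FSA detector when its frontal ids are set
to "auto".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNASSIGNED = "unassigned"


@dataclass
class StateAnnotation:
    names: list[str]                    # per consensus state
    roi_means: np.ndarray               # (n_states, n_rois) mean z per ROI
    frontal_ids: list[int]


def annotate_consensus(
    consensus_maps: np.ndarray,
    roi_labels: np.ndarray,
    roi_groups: dict[int, tuple[str, str]],
    ambiguity_ratio: float = 1.2,
    hemispheric_fraction: float = 0.75,
) -> StateAnnotation:
    """Name each consensus state by its dominant ROI group.

    Per state, the mean z-score inside each ROI is computed; the state is
    named after the ROI group with the highest mean. A state whose top
    group does not exceed the runner-up by ``ambiguity_ratio`` (on
    baseline-shifted activity) is left unassigned and excluded from the
    automatic frontal ids. A state whose activity mass is concentrated in
    one hemisphere across at least two ROI groups is named hemispheric.
    """
    roi_ids = sorted(roi_groups)
    n_states = consensus_maps.shape[0]
    roi_means = np.zeros((n_states, len(roi_ids)))
    names: list[str] = []
    groups = sorted({g for _, g in roi_groups.values()})
    for s in range(n_states):
        m = consensus_maps[s]
        for j, rid in enumerate(roi_ids):
            sel = roi_labels == rid
            roi_means[s, j] = m[sel].mean() if sel.any() else 0.0
        shifted = roi_means[s] - roi_means[s].min()
        group_score = {g: max(shifted[j] for j, rid in enumerate(roi_ids)
                              if roi_groups[rid][1] == g) for g in groups}
        ranked = sorted(group_score.items(), key=lambda kv: -kv[1])
        top, second = ranked[0], ranked[1]
        no_contrast = top[1] <= 1e-12 * max(abs(roi_means[s]).max(), 1.0)
        if no_contrast or (second[1] > 0
                           and top[1] / max(second[1], 1e-12) < ambiguity_ratio):
            names.append(UNASSIGNED)
            continue
        # hemispheric: activity concentrated on one side across >= 2 groups
        side_score = {side: 0.0 for side in ("left", "right")}
        side_groups = {side: set() for side in ("left", "right")}
        for j, rid in enumerate(roi_ids):
            nm, grp = roi_groups[rid]
            for side in ("left", "right"):
                if side in nm:
                    side_score[side] += shifted[j]
                    if shifted[j] > 0.5 * top[1]:
                        side_groups[side].add(grp)
        tot = side_score["left"] + side_score["right"]
        hemi = None
        for side in ("left", "right"):
            if (tot > 0 and side_score[side] / tot >= hemispheric_fraction
                    and len(side_groups[side]) >= 2):
                hemi = side
        names.append("hemispheric" if hemi else top[0])
    frontal_ids = [s for s, nm in enumerate(names) if nm == "frontal"]
    return StateAnnotation(names=names, roi_means=roi_means,
                           frontal_ids=frontal_ids)


def resolve_frontal_ids(
    annotation: StateAnnotation | None,
    frontal_ids: list[int] | str = "auto",
) -> list[int]:
    """Frontal state ids for the FSA detector ("auto" uses the annotation)."""
    if frontal_ids != "auto":
        return list(frontal_ids)
    if annotation is None or not annotation.frontal_ids:
        raise ValueError(
            "no consensus state annotated frontal: pass explicit frontal ids")
    return annotation.frontal_ids
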