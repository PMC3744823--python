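"""Component selection and cross-decomposition matching.

Replaces visual inspection of ICA components with reproducible template
matching: named template maps claim components by maximal absolute spatial
correlation, solved as a global one-to-one assignment; independently
fitted decompositions (e.g., train vs test) are matched the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["TemplateSet", "SelectionResult", "select_components", "match_components"]


@dataclass
class TemplateSet:
    """Named template maps on the analysis grid.

    ``templates`` maps a label to a flattened voxel weight map;
    components correlating (in absolute value) below
    ``selection_threshold`` with their best template are left unselected.
    """

    templates: dict
    selection_threshold: float = 0.4

    def __post_init__(self) -> None:
        self.templates = {k: np.asarray(v, float).ravel() for k, v in self.templates.items()}
        sizes = {v.size for v in self.templates.values()}
        if len(sizes) > 1:
            raise ValueError("templates are not all on the same grid")
        if not 0.0 <= self.selection_threshold <= 1.0:
            raise ValueError("selection_threshold must be in [0, 1]")

    @property
    def labels(self) -> list:
        return list(self.templates.keys())

    def as_matrix(self) -> np.ndarray:
        return np.vstack([self.templates[k] for k in self.labels])


@dataclass
class SelectionResult:
    """Outcome of template-based component selection."""

    labels: list                 # template labels, in template order
    indices: list                # selected component index per label
    correlations: list           # |r| of each assignment
    unselected: list = field(default_factory=list)   # labels below threshold

    def to_dict(self) -> dict:
        return {
            "selected": [
                {"label": l, "component": int(i), "correlation": float(c)}
                for l, i, c in zip(self.labels, self.indices, self.correlations)
            ],
            "unselected": list(self.unselected),
        }


def _abs_corr_matrix(A: np.ndarray, B: np.ndarray, signed: bool = False) -> np.ndarray:
    """Row-by-row Pearson correlation of two map stacks."""
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    An = np.linalg.norm(Az, axis=1, keepdims=True)
    Bn = np.linalg.norm(Bz, axis=1, keepdims=True)
    An[An == 0] = 1.0
    Bn[Bn == 0] = 1.0
    R = (Az / An) @ (Bz / Bn).T
    return R if signed else np.abs(R)


def select_components(results, templates: TemplateSet) -> SelectionResult:
    """Assign group components to templates by absolute spatial correlation.

    The assignment is solved globally (optimal one-to-one assignment
    maximizing total |r|), so no component is ever claimed twice;
    assignments with |r| below the selection threshold are dropped.
    Output order follows template order.

    ``results`` may be a :class:`~fnconn.gica.GroupICAResults` or a plain
    (K, voxels) map array.
    """
    maps = results.group_maps if hasattr(results, "group_maps") else np.asarray(results, float)
    tmpl = templates.as_matrix()
    if tmpl.shape[1] != maps.shape[1]:
        raise ValueError("template grid does not match component maps")
    R = _abs_corr_matrix(tmpl, maps)
    rows, cols = linear_sum_assignment(-R)
    chosen = {int(r): (int(c), float(R[r, c])) for r, c in zip(rows, cols)}
    labels, indices, corrs, unselected = [], [], [], []
    for t, label in enumerate(templates.labels):
        comp, r = chosen[t]
        if r < templates.selection_threshold:
            unselected.append(label)
        else:
            labels.append(label)
            indices.append(comp)
            corrs.append(r)
    return SelectionResult(labels=labels, indices=indices, correlations=corrs,
                           unselected=unselected)


def match_components(train_results, test_results, selected,
                     min_mean_corr: float = 0.3) -> dict:
    """One-to-one matching of a training decomposition's selected
    components to a test decomposition by maximum spatial correlation.

    Returns
    -------
    dict with
        ``mapping``: {train index -> test index},
        ``correlation``: {train index -> |r| of the matched pair},
        ``sign``: {train index -> +1/-1, sign of the matched correlation}
        (used to align the test component's orientation with training).
    """
    tr_maps = train_results.group_maps if hasattr(train_results, "group_maps") \
        else np.asarray(train_results, float)
    te_maps = test_results.group_maps if hasattr(test_results, "group_maps") \
        else np.asarray(test_results, float)
    if tr_maps.shape[1] != te_maps.shape[1]:
        raise ValueError("train/test decompositions are on different grids")
    selected = list(selected)
    Rs = _abs_corr_matrix(tr_maps[selected], te_maps, signed=True)
    R = np.abs(Rs)
    rows, cols = linear_sum_assignment(-R)
    mapping, corr, sign = {}, {}, {}
    for r, c in zip(rows, cols):
        ti = selected[r]
        mapping[ti] = int(c)
        corr[ti] = float(R[r, c])
        sign[ti] = int(np.sign(Rs[r, c])) or 1
    mean_r = float(np.mean(list(corr.values())))
    if mean_r < min_mean_corr:
        warnings.warn(
            f"mean matched correlation {mean_r:.2f} below {min_mean_corr}; "
            "decompositions may not share these networks"
        )
    return {"mapping": mapping, "correlation": corr, "sign": sign}
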