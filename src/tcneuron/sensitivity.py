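"""Local sensitivity analysis: elasticities, ranking, clustering.

Each parameter is perturbed one at a time by a small relative amount
(default +-2.5%) and the electrical features are re-extracted.  The
sensitivity (elasticity) of feature y to parameter p is the central
difference of the baseline-normalized feature over the relative
parameter change:

    S = [(y+ - y-) / y0] / (2 delta)

so S = 2 means a 3% parameter change moves the feature by 6%.  The
N x M matrix of elasticities (N features, M parameters) is ranked by
row/column 2-norms and clustered with the sign- and magnitude-blind
angular distance D = 1 - |cos theta|.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cell.model import CellModel
from .cell.simulate import SimulationError
from .efeatures import TargetSet
from .stimuli import make_battery
from .synthetic_data.population import evaluate_objectives

__all__ = [
    "SensitivityMatrix",
    "elasticity",
    "elasticities",
    "sensitivity_matrix",
    "rank",
    "angular_distance_matrix",
    "cluster",
]

DEFAULT_DELTA = 0.025


@dataclass
class SensitivityMatrix:
    """Elasticities with labels; NaN marks entries that could not be
    computed (failed perturbed simulation or feature undefined)."""

    values: np.ndarray  # N features x M parameters
    features: List[str]
    parameters: List[str]
    delta: float = DEFAULT_DELTA
    zero_baseline: np.ndarray = field(default=None)  # rows using absolute change

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.parameters)):
            raise ValueError("matrix shape must match labels")
        if self.zero_baseline is None:
            self.zero_baseline = np.zeros(len(self.features), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features,
                            columns=self.parameters)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def elasticity(f: Callable[[float], float], p0: float,
               delta: float = DEFAULT_DELTA) -> float:
    """Elasticity of a scalar feature f at parameter value p0.

    Central difference at p0 (1 +- delta), normalized by f(p0); exact
    for power laws (f = p^k gives k).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    y0 = f(p0)
    yp = f(p0 * (1.0 + delta))
    ym = f(p0 * (1.0 - delta))
    if y0 == 0:
        return (yp - ym) / (2.0 * delta)
    return ((yp - ym) / y0) / (2.0 * delta)


def elasticities(feature_fn: Callable[[np.ndarray], Dict[str, Optional[float]]],
                 p0: np.ndarray,
                 parameter_names: Sequence[str],
                 delta: float = DEFAULT_DELTA) -> SensitivityMatrix:
    """Elasticity matrix of a vector-valued feature map.

    ``feature_fn`` maps a full parameter vector to named feature
    values (None = undefined).  Zero-baseline features fall back to
    the absolute central difference and are flagged.
    """
    p0 = np.asarray(p0, dtype=float)
    base = feature_fn(p0)
    feature_names = list(base)
    N, M = len(feature_names), len(p0)
    vals = np.full((N, M), np.nan)
    zero_rows = np.zeros(N, dtype=bool)
    for j in range(M):
        pp, pm = p0.copy(), p0.copy()
        pp[j] = p0[j] * (1.0 + delta)
        pm[j] = p0[j] * (1.0 - delta)
        try:
            fp = feature_fn(pp)
            fm = feature_fn(pm)
        except SimulationError:
            continue  # entries stay NaN (marked missing)
        for i, name in enumerate(feature_names):
            y0, yp, ym = base[name], fp.get(name), fm.get(name)
            if yp is None or ym is None or y0 is None:
                continue
            if y0 == 0:
                vals[i, j] = (yp - ym) / (2.0 * delta)
                zero_rows[i] = True
            else:
                vals[i, j] = ((yp - ym) / y0) / (2.0 * delta)
    return SensitivityMatrix(vals, feature_names, list(parameter_names),
                             delta, zero_rows)


def sensitivity_matrix(cell: CellModel, targets: TargetSet,
                       delta: float = DEFAULT_DELTA,
                       free_names: Optional[Sequence[str]] = None) -> SensitivityMatrix:
    """Elasticities of the target-set features w.r.t. the free parameters.

    Each parameter is varied by +-delta of its optimized value; the
    battery protocols the targets reference are re-simulated and the
    features re-extracted.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    battery = make_battery(targets.i_thr, targets.i_hold_tonic,
                           targets.i_hold_burst)
    objectives = [(t.protocol, t.feature) for t in targets]
    names = list(cell.params.names)
    free = list(free_names or [n for n in names if not n.endswith(".unused")])
    free_idx = np.array([names.index(n) for n in free])

    def feature_fn(x: np.ndarray) -> Dict[str, Optional[float]]:
        vals = cell.params.values.copy()
        vals[free_idx] = x
        c = cell.with_params(cell.params.with_values(vals))
        feats = evaluate_objectives(c, battery, objectives)
        return {f"{p}|{f}": v for (p, f), v in feats.items()}

    return elasticities(feature_fn, cell.params.values[free_idx], free, delta)


def rank(matrix: SensitivityMatrix) -> Tuple[List[str], List[str]]:
    """(parameters by descending column norm, features by row norm).

    Missing entries are excluded from the norms.
    """
    vals = np.where(np.isfinite(matrix.values), matrix.values, 0.0)
    col = np.sqrt(np.sum(vals**2, axis=0))
    row = np.sqrt(np.sum(vals**2, axis=1))
    params = [matrix.parameters[i] for i in np.argsort(-col, kind="stable")]
    feats = [matrix.features[i] for i in np.argsort(-row, kind="stable")]
    return params, feats


def angular_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise D = 1 - |cos theta| between row vectors; D in [0, 1].

    Sign- and magnitude-independent: parallel and anti-parallel
    vectors are at distance 0, orthogonal ones at 1.  Zero vectors are
    put at distance 1 from everything (singletons), with a warning.
    """
    V = np.where(np.isfinite(vectors), vectors, 0.0)
    norms = np.linalg.norm(V, axis=1)
    zero = norms == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero vector(s) assigned to "
                      "singleton clusters", stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    U = V / safe[:, None]
    cos = np.clip(np.abs(U @ U.T), 0.0, 1.0)
    D = 1.0 - cos
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    np.fill_diagonal(D, 0.0)
    return D


def cluster(matrix: SensitivityMatrix, axis: str = "features",
            n_clusters: Optional[int] = None):
    """Agglomerative (average-linkage) clustering of rows or columns.

    Returns (labels, flat cluster ids, linkage matrix).  ``axis`` is
    "features" (rows) or "parameters" (columns).
    """
    if axis == "features":
        vectors, labels = matrix.values, matrix.features
    elif axis == "parameters":
        vectors, labels = matrix.values.T, matrix.parameters
    else:
        raise ValueError("axis must be 'features' or 'parameters'")
    D = angular_distance_matrix(np.asarray(vectors, float))
    Z = linkage(squareform(D, checks=False), method="average")
    k = n_clusters or max(2, int(np.sqrt(len(labels))))
    flat = fcluster(Z, t=min(k, len(labels)), criterion="maxclust")
    return list(labels), flat, Z
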