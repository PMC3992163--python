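"""Local profile alignment and the diversity scores.

Two LAD profiles are compared with a Smith-Waterman local alignment in
which the substitution score for positions *i*, *j* is inversely related
to the absolute LAD difference,

    sigma(i, j) = s_max - |LAD_i - LAD_j| / m0,

with a linear gap penalty ``g``.  The aligned pairs give the number of
equivalent residues ``Ne`` and the RMSD of LAD values over those pairs,
which the diversity score combines as

    LAD_div = 1 - (Ne / mean(NQ, NS)) * 1 / (1 + (RMSD / D)^alpha),

a dissimilarity in [0, 1]: 0 for identical profiles covering both chains,
1 when nothing aligns.  The trained defaults are (D, alpha) = (1, 4.5)
for ED profiles and (1.1, 5) for GD profiles.

``struct_div`` is the analogous coverage-penalised score for external
coordinate-level alignments (RMSD of aligned C-alpha atoms):

    Struct_div = RMSD / (Ne / mean(NQ, NS))^1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Trained diversity parameters per metric.
DEFAULT_PARAMS = {"ED": (1.0, 4.5), "GD": (1.1, 5.0)}

DEFAULT_MATCH_SCALE = 1.0  # m0, Å per score unit
DEFAULT_MATCH_OFFSET = 1.0  # s_max
DEFAULT_GAP_PENALTY = 0.5  # g, per gapped position

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class DiversityParams:
    """Scale ``D`` (Å) and exponent ``alpha`` of the RMSD weighting."""

    D: float
    alpha: float

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")

    @classmethod
    def for_metric(cls, metric: str) -> "DiversityParams":
        return cls(*DEFAULT_PARAMS[metric.upper()])


@dataclass
class ProfileAlignment:
    """Result of aligning two LAD profiles."""

    pairs: list[tuple[int, int]]  # aligned (query index, subject index)
    score: float
    NQ: int
    NS: int
    lad_rmsd: float
    lad_div: float | None = None

    @property
    def Ne(self) -> int:
        return len(self.pairs)


def _substitution_matrix(q: np.ndarray, s: np.ndarray, s_max: float, m0: float) -> np.ndarray:
    return s_max - np.abs(q[:, None] - s[None, :]) / m0


def _sw_matrix(sigma: np.ndarray, gap: float) -> np.ndarray:
    """Smith-Waterman score matrix with linear gaps, vectorised per row.

    Within a row, a chain of left-gaps obeys the linear recurrence
    ``m[j] = max(c[j], m[j-1] - g)`` which equals
    ``cummax(c[j] + g*j) - g*j`` — that running maximum lets each row be
    filled with O(n) numpy operations.
    """
    nq, ns = sigma.shape
    H = np.zeros((nq + 1, ns + 1))
    gj = gap * np.arange(1, ns + 1)
    for i in range(1, nq + 1):
        c = np.maximum(0.0, H[i - 1, :-1] + sigma[i - 1])
        c = np.maximum(c, H[i - 1, 1:] - gap)
        H[i, 1:] = np.maximum.accumulate(c + gj) - gj
    return H


def _traceback(H: np.ndarray, sigma: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Recover one optimal local path; ties prefer diagonal, then up, then left."""
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0 and H[i, j] > _TIE_TOL:
        h = H[i, j]
        if abs(h - (H[i - 1, j - 1] + sigma[i - 1, j - 1])) <= _TIE_TOL and H[i - 1, j - 1] >= 0:
            pairs.append((int(i - 1), int(j - 1)))
            i, j = i - 1, j - 1
        elif abs(h - (H[i - 1, j] - gap)) <= _TIE_TOL:
            i -= 1
        elif abs(h - (H[i, j - 1] - gap)) <= _TIE_TOL:
            j -= 1
        else:  # pragma: no cover - numerical safety net
            break
    pairs.reverse()
    return pairs


def align_profiles(
    q,
    s,
    match_scale: float = DEFAULT_MATCH_SCALE,
    match_offset: float = DEFAULT_MATCH_OFFSET,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    params: DiversityParams | None = None,
) -> ProfileAlignment:
    """Optimal local alignment of two LAD profiles.

    Both profiles must share metric and window.  Returns the aligned index
    pairs, ``Ne``, the RMSD of LAD values over aligned pairs, and — when
    ``params`` is given (or derivable from the metric) — the LAD_div score.
    An all-negative scoring regime yields an empty alignment (``Ne = 0``),
    not an error.
    """
    if len(q) == 0 or len(s) == 0:
        raise ValueError("profiles must be non-empty")
    if q.metric != s.metric:
        raise ValueError(f"metric mismatch: {q.metric} vs {s.metric}")
    if q.window != s.window:
        raise ValueError(f"window mismatch: {q.window} vs {s.window}")

    qv, sv = q.values, s.values
    sigma = _substitution_matrix(qv, sv, match_offset, match_scale)
    H = _sw_matrix(sigma, gap_penalty)
    score = float(H.max())
    pairs = _traceback(H, sigma, gap_penalty) if score > _TIE_TOL else []

    if pairs:
        deltas = np.array([qv[a] - sv[b] for a, b in pairs])
        rmsd = float(np.sqrt(np.mean(deltas**2)))
    else:
        rmsd = float("inf")

    aln = ProfileAlignment(pairs=pairs, score=score, NQ=len(q), NS=len(s), lad_rmsd=rmsd)
    if params is None:
        params = DiversityParams.for_metric(q.metric)
    aln.lad_div = lad_div(aln.Ne, rmsd if math.isfinite(rmsd) else 0.0, aln.NQ, aln.NS, params)
    if aln.Ne == 0:
        aln.lad_div = 1.0
    return aln


def lad_div(Ne: int, lad_rmsd: float, NQ: int, NS: int, params: DiversityParams) -> float:
    """Diversity of two LAD profiles, in [0, 1]; smaller = more similar.

    ``lad_rmsd`` is the RMSD of *LAD values* over aligned residues (not a
    coordinate RMSD).
    """
    if NQ == 0 and NS == 0:
        raise ValueError("both profile lengths are zero")
    if Ne < 0 or lad_rmsd < 0:
        raise ValueError("Ne and lad_rmsd must be non-negative")
    mean_n = 0.5 * (NQ + NS)
    value = 1.0 - (Ne / mean_n) / (1.0 + (lad_rmsd / params.D) ** params.alpha)
    return float(min(max(value, 0.0), 1.0))


def struct_div(rmsd: float, Ne: int, NQ: int, NS: int) -> float:
    """Coverage-penalised diversity for coordinate-level alignments.

    ``rmsd`` here is the RMSD of aligned C-alpha atoms in Å.  ``Ne = 0``
    (nothing aligned) maps to +inf, the worst possible score.
    """
    if Ne == 0:
        return float("inf")
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    mean_n = 0.5 * (NQ + NS)
    return float(rmsd / (Ne / mean_n) ** 1.5)


DEFAULT_D_GRID = np.round(np.arange(0.1, 20.0 + 1e-9, 0.1), 10)
DEFAULT_ALPHA_GRID = np.round(np.arange(1.0, 5.0 + 1e-9, 0.5), 10)


def tune_diversity_params(
    positive_pairs,
    negative_pairs,
    D_grid=DEFAULT_D_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
) -> DiversityParams:
    """Grid-search (D, alpha) separating positive from negative pairs at 0.5.

    Each pair carries ``(Ne, lad_rmsd, NQ, NS)``.  The objective is the
    number of positives with LAD_div < 0.5 plus the number of negatives
    with LAD_div >= 0.5; ties resolve to the smallest D, then smallest
    alpha.  The default grids evaluate 200 x 9 = 1800 combinations.
    """
    if not len(positive_pairs) or not len(negative_pairs):
        raise ValueError("positive and negative pair sets must be non-empty")
    D_grid = np.asarray(D_grid, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if D_grid.size == 0 or alpha_grid.size == 0:
        raise ValueError("grids must be non-empty")

    def unpack(pairs):
        arr = np.array([(p[0], p[1], p[2], p[3]) for p in pairs], dtype=float)
        ne, rmsd, nq, ns = arr.T
        return ne / (0.5 * (nq + ns)), rmsd

    pos_cov, pos_rmsd = unpack(positive_pairs)
    neg_cov, neg_rmsd = unpack(negative_pairs)

    best = None
    for D in D_grid:
        for alpha in alpha_grid:
            pos_div = 1.0 - pos_cov / (1.0 + (pos_rmsd / D) ** alpha)
            neg_div = 1.0 - neg_cov / (1.0 + (neg_rmsd / D) ** alpha)
            objective = int((pos_div < 0.5).sum() + (neg_div >= 0.5).sum())
            key = (-objective, D, alpha)
            if best is None or key < best[0]:
                best = (key, DiversityParams(float(D), float(alpha)))
    return best[1]
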