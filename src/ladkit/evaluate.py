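"""Retrieval-style evaluation of the descriptor.

A query profile is compared to every database profile by LAD_div and the
database is sorted ascending (most similar first).  Standard
information-retrieval statistics summarise the rankings: rank-1 success
rate against group representatives, R-precision, (mean) average
precision, the 11-point interpolated precision-recall curve, and the
F1-measure at a rank cutoff (the comparison protocol of record uses the
top 64 retrieved structures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import DiversityParams, align_profiles

DEFAULT_F1_CUTOFF = 64  # top-k used in the cross-method F1 protocol


@dataclass
class RetrievalRun:
    """One query's ranking over the database, plus its relevance labels."""

    query_id: str
    ranking: list[tuple[str, float]]  # (subject_id, lad_div) ascending
    relevant: set[str] = field(default_factory=set)

    def __post_init__(self):
        ids = [sid for sid, _ in self.ranking]
        if len(ids) != len(set(ids)):
            raise ValueError("ranking contains duplicate subject ids")

    @property
    def n_relevant(self) -> int:
        return len(self.relevant & {sid for sid, _ in self.ranking})


@dataclass
class MetricsReport:
    success_rate: float
    r_precision: float
    map: float
    f1_at_k: float
    interpolated_pr_curve: list[float]

    def to_dict(self) -> dict:
        return {
            "success_rate": self.success_rate,
            "r_precision": self.r_precision,
            "map": self.map,
            "f1_at_k": self.f1_at_k,
            "interpolated_pr_curve": list(self.interpolated_pr_curve),
        }


def rank_database(query, db, params: DiversityParams | None = None,
                  relevant: set[str] | None = None, **align_kwargs) -> RetrievalRun:
    """Rank database profiles against a query by ascending LAD_div.

    The query is never compared to itself (same ``structure_id``).  Ties in
    LAD_div are broken lexicographically by subject id for reproducibility.
    """
    if not db:
        raise ValueError("database is empty")
    scored = []
    for subject in db:
        if subject.structure_id == query.structure_id:
            continue
        aln = align_profiles(query, subject, params=params, **align_kwargs)
        scored.append((subject.structure_id, float(aln.lad_div)))
    scored.sort(key=lambda t: (t[1], t[0]))
    return RetrievalRun(query_id=query.structure_id, ranking=scored,
                        relevant=set(relevant or ()))


def _relevance_flags(run: RetrievalRun) -> list[bool]:
    return [sid in run.relevant for sid, _ in run.ranking]


def interpolated_pr(run: RetrievalRun) -> list[float]:
    """11-point interpolated precision at recall 0.0, 0.1, ..., 1.0.

    Interpolated precision at recall level r is the maximum precision
    achieved at any recall r' >= r.
    """
    flags = _relevance_flags(run)
    total = sum(flags)
    if total == 0:
        raise ValueError("run has no relevant items")
    precisions, recalls = [], []
    tp = 0
    for rank, rel in enumerate(flags, start=1):
        if rel:
            tp += 1
            precisions.append(tp / rank)
            recalls.append(tp / total)
    points = []
    for level in (x / 10 for x in range(11)):
        candidates = [p for p, r in zip(precisions, recalls) if r >= level - 1e-12]
        points.append(max(candidates) if candidates else 0.0)
    return points


def r_precision(run: RetrievalRun) -> float:
    """Fraction of relevant items within the top R ranks, R = #relevant."""
    flags = _relevance_flags(run)
    R = sum(flags)
    if R == 0:
        raise ValueError("run has no relevant items")
    return sum(flags[:R]) / R


def average_precision(run: RetrievalRun) -> float:
    """Mean of precision at each relevant item's rank."""
    flags = _relevance_flags(run)
    total = sum(flags)
    if total == 0:
        raise ValueError("run has no relevant items")
    tp = 0
    precs = []
    for rank, rel in enumerate(flags, start=1):
        if rel:
            tp += 1
            precs.append(tp / rank)
    return sum(precs) / total


def mean_average_precision(runs) -> float:
    runs = list(runs)
    if not runs:
        raise ValueError("no runs")
    return sum(average_precision(r) for r in runs) / len(runs)


def f1_at_k(run: RetrievalRun, k: int = DEFAULT_F1_CUTOFF) -> float:
    """F1 = 2PR/(P+R) with precision and recall computed on the top k only."""
    if k < 1:
        raise ValueError("k must be >= 1")
    flags = _relevance_flags(run)
    total = sum(flags)
    tp = sum(flags[:k])
    precision = tp / min(k, len(flags)) if flags else 0.0
    recall = tp / total if total else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def success_rate(runs, representative_of: dict[str, str]) -> float:
    """Fraction of queries whose group representative sits at rank 1.

    ``representative_of`` maps each query id to its group's representative
    structure id; a query without one is an error.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs")
    hits = 0
    for run in runs:
        rep = representative_of.get(run.query_id)
        if rep is None:
            raise ValueError(f"query {run.query_id} has no group representative")
        if run.ranking and run.ranking[0][0] == rep:
            hits += 1
    return hits / len(runs)


def evaluate_runs(runs, representative_of: dict[str, str], k: int = DEFAULT_F1_CUTOFF,
                  rep_runs=None) -> MetricsReport:
    """All retrieval metrics for a set of ranked queries.

    ``runs`` rank each query against the full database and feed the
    PR/MAP/F1 statistics; ``rep_runs`` (rankings against the group
    representatives only) feed the rank-1 success rate and default to
    ``runs`` when the two protocols coincide.
    """
    runs = list(runs)
    curves = [interpolated_pr(r) for r in runs]
    mean_curve = [sum(c[i] for c in curves) / len(curves) for i in range(11)]
    return MetricsReport(
        success_rate=success_rate(rep_runs if rep_runs is not None else runs, representative_of),
        r_precision=sum(r_precision(r) for r in runs) / len(runs),
        map=mean_average_precision(runs),
        f1_at_k=sum(f1_at_k(r, k) for r in runs) / len(runs),
        interpolated_pr_curve=mean_curve,
    )


# ---------------------------------------------------------------------------
# Group manifests
# ---------------------------------------------------------------------------


def read_manifest(src) -> pd.DataFrame:
    """Read a morph-group manifest TSV: structure_id, group_id, is_representative."""
    df = pd.read_csv(src, sep="\t", dtype={"structure_id": str, "group_id": str})
    required = {"structure_id", "group_id", "is_representative"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df["is_representative"] = df["is_representative"].astype(bool)
    return df


def write_manifest(df: pd.DataFrame, dest) -> None:
    df.to_csv(dest, sep="\t", index=False)
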