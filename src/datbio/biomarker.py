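"""Similarity index and the decibel therapy biomarker QB_DAT.

With unit-normalized embeddings the retrieval distance D lies in [0, 2],
and the similarity index is defined as

    S = clamp(1 - D/2, eps, 1),        eps = 1e-6

so S = 1 for identical embeddings and S -> eps for antipodal ones.  The
quantitative biomarker is

    QB_DAT = 10 * log10(1 / S)  dB  =  -10 * log10(S)  dB

which is 0 dB when brain activity during therapy is indistinguishable
from rest and grows without bound as the two diverge; the eps clamp caps
it at 60 dB.  Cohort reports give both the mean of per-pair QB values and
the QB of the mean similarity (the two differ by Jensen's inequality;
the mean of per-pair QB is the headline number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimilarityIndex", "QBReport", "similarity_index", "qb_dat",
           "cohort_report", "permutation_pvalue", "score_pairs"]

#: lower clamp for the similarity index (caps QB_DAT at 60 dB)
EPS_SIMILARITY = 1e-6


@dataclass(frozen=True)
class SimilarityIndex:
    """Unitless pair similarity in (0, 1]; 1 = identical embeddings."""

    S: float
    query_phase: str = ""
    reference_phase: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.S <= 1:
            raise ValueError(f"similarity must lie in (0, 1], got {self.S}")


def similarity_index(distance: float, query_phase: str = "",
                     reference_phase: str = "") -> SimilarityIndex:
    """Map a normalized-embedding distance in [0, 2] to a similarity.

    ``S = clamp(1 - distance/2, eps, 1)``, monotone decreasing in the
    distance.  A distance above 2 violates the unit-normalization
    contract and raises.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance > 2.0 + 1e-9:
        raise ValueError(
            f"distance {distance} exceeds 2; embeddings are not unit-normalized")
    S = min(1.0, max(EPS_SIMILARITY, 1.0 - distance / 2.0))
    return SimilarityIndex(S=S, query_phase=query_phase,
                           reference_phase=reference_phase)


def qb_dat(S: SimilarityIndex | float) -> float:
    """The decibel biomarker ``QB = 10 * log10(1/S)``.

    0 dB at S = 1 (no therapy-induced change), strictly increasing as the
    similarity drops.
    """
    s = S.S if isinstance(S, SimilarityIndex) else float(S)
    if not 0 < s <= 1:
        raise ValueError(f"similarity must lie in (0, 1], got {s}")
    return float(10.0 * np.log10(1.0 / s))


@dataclass
class QBReport:
    """Per-pair similarities/QB values with cohort aggregates.

    ``mean_qb`` is the mean of per-pair QB values (headline);
    ``qb_of_mean`` applies QB to the mean similarity.  Both are reported
    per comparison group (rest-vs-rest, rest-vs-DAT).
    """

    pairs: pd.DataFrame  # columns: group, subject, S, QB_dB
    aggregates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def group_mean_qb(self, group: str) -> float:
        row = self.aggregates.loc[self.aggregates["group"] == group]
        if row.empty:
            raise KeyError(f"no aggregate for group {group!r}")
        return float(row["mean_qb_dB"].iloc[0])

    def group_mean_similarity(self, group: str) -> float:
        row = self.aggregates.loc[self.aggregates["group"] == group]
        if row.empty:
            raise KeyError(f"no aggregate for group {group!r}")
        return float(row["mean_S"].iloc[0])


def cohort_report(pairs: pd.DataFrame) -> QBReport:
    """Aggregate per-pair similarities into a cohort report.

    *pairs* needs columns ``group`` and ``S`` (``subject`` optional);
    ``QB_dB`` is recomputed from S.  Groups without any pair are omitted
    with a warning.
    """
    if "group" not in pairs or "S" not in pairs:
        raise ValueError("pairs must have columns 'group' and 'S'")
    if pairs.empty:
        raise ValueError("no pairs to report")
    pairs = pairs.copy()
    pairs["QB_dB"] = [qb_dat(s) for s in pairs["S"]]
    rows = []
    for group, sub in pairs.groupby("group"):
        if sub.empty:  # defensive; groupby drops empty groups anyway
            warnings.warn(f"group {group!r} is empty; omitted", stacklevel=2)
            continue
        mean_s = float(sub["S"].mean())
        rows.append({
            "group": group,
            "n_pairs": len(sub),
            "mean_S": mean_s,
            "mean_qb_dB": float(sub["QB_dB"].mean()),
            "qb_of_mean_dB": qb_dat(mean_s),
        })
    return QBReport(pairs=pairs, aggregates=pd.DataFrame(rows))


def score_pairs(results, query_epochs, db_epochs, group: str,
                subject: str = "") -> pd.DataFrame:
    """All query-to-database pair similarities under a trained encoder.

    Embeds both sets with the shared weights of *results* (a
    ``SiameseResults``), computes every pairwise retrieval distance, and
    returns one row per (query, database) pair with its similarity index
    and QB value.
    """
    q = results.encode(query_epochs)
    db = results.encode(db_epochs)
    dists = np.linalg.norm(q[:, None, :] - db[None, :, :], axis=2).ravel()
    records = []
    for d in dists:
        S = similarity_index(float(d)).S
        records.append({"group": group, "subject": subject, "S": S,
                        "QB_dB": qb_dat(S)})
    return pd.DataFrame(records)


def permutation_pvalue(a: np.ndarray, b: np.ndarray, n_permutations: int = 1000,
                       seed: int = 0) -> float:
    """One-sided permutation p-value for mean(a) > mean(b).

    Pools the two samples, permutes group assignment, and counts
    permuted mean differences at least as large as the observed one
    (add-one correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = a.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if perm[:n_a].mean() - perm[n_a:].mean() >= observed:
            count += 1
    return (count + 1) / (n_permutations + 1)
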