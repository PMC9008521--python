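"""Rank-turbulence divergence between two ranked type systems.

Given two tied-rank distributions R1 and R2 over (partially)
overlapping supports, each type tau in the union contributes

    delta D_tau = (1/N) * (alpha+1)/alpha * | r1^-alpha - r2^-alpha |^(1/(alpha+1)),

where a type absent from one system receives there the tied rank of a
hypothetical block appended below the observed list:

    r2(tau absent) = N2 + (N_x1 + 1)/2,

with N2 the number of observed types in system 2 and N_x1 the number of
types exclusive to system 1 (and symmetrically).  The normalization N
is the same sum evaluated in the all-disjoint hypothetical — each
system keeps its observed ranks, every type is imputed as fully
exclusive — which pins D into [0, 1]: identical tied rankings give 0,
disjoint supports give exactly 1.  The divergence is symmetric in its
arguments.  The tunable exponent alpha in (0, inf) dials sensitivity
between low-rank (common) and high-rank (rare) types; the instrument
convention alpha = 1/3 is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ngrams import RankedDistribution

DEFAULT_ALPHA = 1.0 / 3.0


def impute_absent_ranks(
    ranks1: RankedDistribution, ranks2: RankedDistribution
) -> pd.DataFrame:
    """Completed (r1, r2) pairs over the union of supports.

    Returns a DataFrame indexed by type with columns ``r1``, ``r2`` and
    ``exclusivity`` in {both, only_1, only_2}.
    """
    if len(ranks1) == 0 or len(ranks2) == 0:
        raise ValueError("both systems must be non-empty")
    r1 = ranks1.df["rank"]
    r2 = ranks2.df["rank"]
    s1, s2 = set(r1.index), set(r2.index)
    n1, n2 = len(s1), len(s2)
    only1 = s1 - s2
    only2 = s2 - s1
    imputed_r2 = n2 + (len(only1) + 1) / 2.0  # rank in system 2 for only_1 types
    imputed_r1 = n1 + (len(only2) + 1) / 2.0

    types = sorted(s1 | s2)
    rows = []
    for t in types:
        in1 = t in s1
        in2 = t in s2
        rows.append(
            (
                float(r1[t]) if in1 else imputed_r1,
                float(r2[t]) if in2 else imputed_r2,
                "both" if (in1 and in2) else ("only_1" if in1 else "only_2"),
            )
        )
    df = pd.DataFrame(rows, columns=["r1", "r2", "exclusivity"], index=pd.Index(types, name="type"))
    return df


@dataclass
class DivergenceResult:
    """Total rank-turbulence divergence with its per-type decomposition.

    ``table`` is sorted by contribution descending, columns ``r1, r2,
    contribution, exclusivity``; ``balance`` summarizes each system's
    share of combined count mass, of union types, and of exclusive
    types.
    """

    alpha: float
    total: float
    normalization: float
    table: pd.DataFrame
    balance: dict

    @property
    def D(self) -> float:
        return self.total


def _term(r_a: np.ndarray, r_b: np.ndarray, alpha: float) -> np.ndarray:
    pref = (alpha + 1.0) / alpha
    return pref * np.abs(r_a**-alpha - r_b**-alpha) ** (1.0 / (alpha + 1.0))


def rank_turbulence_divergence(
    ranks1: RankedDistribution,
    ranks2: RankedDistribution,
    alpha: float = DEFAULT_ALPHA,
) -> DivergenceResult:
    """Normalized rank-turbulence divergence between two systems."""
    if not (alpha > 0 and math.isfinite(alpha)):
        raise ValueError("alpha must be a finite positive real")
    pairs = impute_absent_ranks(ranks1, ranks2)
    contrib_un = _term(pairs["r1"].to_numpy(), pairs["r2"].to_numpy(), alpha)

    n1, n2 = len(ranks1), len(ranks2)
    # all-disjoint hypothetical: observed ranks vs full-exclusivity imputation
    disj_r2 = n2 + (n1 + 1) / 2.0
    disj_r1 = n1 + (n2 + 1) / 2.0
    norm = float(
        _term(ranks1.df["rank"].to_numpy(), np.full(n1, disj_r2), alpha).sum()
        + _term(np.full(n2, disj_r1), ranks2.df["rank"].to_numpy(), alpha).sum()
    )

    table = pairs.copy()
    table["contribution"] = contrib_un / norm
    table = table.sort_values(
        by=["contribution", "type"], ascending=[False, True],
        key=lambda s: s if s.name == "contribution" else s,
    )[["r1", "r2", "contribution", "exclusivity"]]
    total = float(table["contribution"].sum())

    c1 = ranks1.df["count"].sum()
    c2 = ranks2.df["count"].sum()
    n_types = len(pairs)
    excl1 = int((pairs["exclusivity"] == "only_1").sum())
    excl2 = int((pairs["exclusivity"] == "only_2").sum())
    balance = {
        "system_1": {
            "pct_total_counts": 100.0 * c1 / (c1 + c2),
            "pct_all_types": 100.0 * n1 / n_types,
            "pct_exclusive_types": 100.0 * excl1 / n_types,
        },
        "system_2": {
            "pct_total_counts": 100.0 * c2 / (c1 + c2),
            "pct_all_types": 100.0 * n2 / n_types,
            "pct_exclusive_types": 100.0 * excl2 / n_types,
        },
    }
    return DivergenceResult(
        alpha=alpha, total=total, normalization=norm, table=table, balance=balance
    )


def filter_anchor_phrases(
    dist: RankedDistribution, anchor_phrase: str
) -> RankedDistribution:
    """Drop 3-grams beginning or ending with the anchor 2-gram, then
    re-rank the survivors (counts unchanged)."""
    anchor = tuple(anchor_phrase.lower().split())
    if len(anchor) != 2:
        raise ValueError("anchor must be a 2-gram")

    def keep(gram: str) -> bool:
        toks = tuple(gram.split())
        if len(toks) < 3:
            return True
        return toks[:2] != anchor and toks[-2:] != anchor

    counts = {
        g: int(c) for g, c in dist.df["count"].items() if keep(g)
    }
    if not counts:
        raise ValueError("no n-grams survive the anchor filter")
    return RankedDistribution.from_counts(counts, label=dist.label, n=dist.n)


@dataclass
class RankRankHistogram:
    """2D histogram over (log10 r1, log10 r2) plus exclusive bands.

    ``cells`` has columns ``cell_x, cell_y, count, band`` where band is
    ``main`` for shared types and ``only_1`` / ``only_2`` for types
    binned on their single observed coordinate.  Cell indices are
    floor(log10 r / cell_size).
    """

    cell_size: float
    cells: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.cells["count"].sum())


def rank_rank_histogram(
    pairs: pd.DataFrame, cell_size: float = 0.25
) -> RankRankHistogram:
    """Bin completed rank pairs (from :func:`impute_absent_ranks`) onto
    the log-rank grid; exclusive types go to their band keyed by the
    observed coordinate."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")

    def cell(r: float) -> int:
        return int(math.floor(math.log10(r) / cell_size))

    counts: dict[tuple[int, int, str], int] = {}
    for t, row in pairs.iterrows():
        band = row["exclusivity"]
        if band == "both":
            key = (cell(row["r1"]), cell(row["r2"]), "main")
        elif band == "only_1":
            key = (cell(row["r1"]), -1, "only_1")
        else:
            key = (-1, cell(row["r2"]), "only_2")
        counts[key] = counts.get(key, 0) + 1
    cells = pd.DataFrame(
        [(x, y, c, b) for (x, y, b), c in sorted(counts.items(), key=lambda kv: (kv[0][2], kv[0][0], kv[0][1]))],
        columns=["cell_x", "cell_y", "count", "band"],
    )
    return RankRankHistogram(cell_size=cell_size, cells=cells)
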