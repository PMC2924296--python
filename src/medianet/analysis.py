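"""Results-level summaries over the effect indices.

Mediator ranking, most-influenced proteins, per-disease influence
decomposition, and the functional-importance helper that relates a protein's
mediation strength M^2 to the average enrichment P-value (avP) of the
functional terms annotated to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .effects import DiseasePairEffect, MediatorTable, effect_matrix
from .network import InteractionNetwork

__all__ = [
    "InfluenceBreakdown",
    "rank_mediators",
    "most_influenced",
    "influence_decomposition",
    "read_term_table",
    "average_term_pvalue",
    "correlate",
    "mediator_function_correlation",
]


def rank_mediators(
    table: MediatorTable, top: int | None = None
) -> list[tuple[str, float]]:
    """Mediators sorted by total mediation strength M^2, descending.

    Ties break lexicographically on the protein id so the ranking is
    deterministic. ``top`` truncates the list; it must be >= 1 if given.
    """
    if top is not None and top < 1:
        raise ValueError("top must be >= 1")
    ranked = sorted(table.totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top] if top is not None else ranked


def most_influenced(
    pair_effect: DiseasePairEffect, side: str = "receiver"
) -> str | None:
    """The protein with the largest aggregate cross-set effect.

    side="receiver": the receiver with the largest summed incoming effect
    (row sum of the contribution matrix). side="source": the source with the
    largest summed outgoing effect (column sum). Returns None when the
    matrix is all-zero (no linkage at this step count).
    """
    if side not in ("receiver", "source"):
        raise ValueError(f"side must be 'receiver' or 'source', got {side!r}")
    contrib = pair_effect.contributions
    if contrib.empty:
        raise ValueError("contribution matrix is empty")
    sums = contrib.sum(axis=1) if side == "receiver" else contrib.sum(axis=0)
    if float(sums.max()) == 0.0:
        return None
    # idxmax with deterministic lexicographic tie-break
    best = sums[sums == sums.max()].index
    return sorted(best)[0]


@dataclass
class InfluenceBreakdown:
    """Decomposition of the total incoming effect on one protein by source set.

    ``percentages`` sum to 100 when any contribution is positive; when every
    source set contributes zero the percentages are undefined and
    ``defined`` is False.
    """

    target: str
    n: int
    contributions: dict[str, float]
    percentages: dict[str, float] | None

    @property
    def defined(self) -> bool:
        return self.percentages is not None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, c in sorted(self.contributions.items()):
            rows.append(
                {
                    "target": self.target,
                    "label": label,
                    "contribution": c,
                    "percent": self.percentages[label] if self.percentages else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def influence_decomposition(
    net: InteractionNetwork,
    target: str,
    source_sets: Mapping[str, Iterable[str]],
    n: int = 2,
) -> InfluenceBreakdown:
    """Share of the n-step influence on *target* contributed by each labeled set.

    contribution_m = sum over j in S_m of a^n_{target, j}; the percentage is
    each contribution over the total across sets. The target is dropped from
    any source set containing it (self-influence is excluded), with a
    warning-level note in the result rather than an error.
    """
    net._require(target)
    m = effect_matrix(net, n)
    contributions: dict[str, float] = {}
    for label, members in source_sets.items():
        members = {p for p in members if p != target}
        net._require(*members)
        contributions[label] = float(
            sum(m.loc(target, j) for j in members)
        )
    total = sum(contributions.values())
    if total > 0:
        percentages = {k: 100.0 * v / total for k, v in contributions.items()}
    else:
        percentages = None
    return InfluenceBreakdown(
        target=target, n=n, contributions=contributions, percentages=percentages
    )


def read_term_table(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read a flat functional-term table (DAVID-export-like TSV).

    Columns: protein_id, category, term, count, p_value; comment lines start
    with ``#``. P-values must lie in (0, 1].
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"protein_id", "category", "term", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"term table missing column(s): {sorted(missing)}")
    bad = df[(df["p_value"] <= 0) | (df["p_value"] > 1)]
    if not bad.empty:
        raise ValueError(
            f"{len(bad)} term row(s) with P-value outside (0, 1]"
        )
    return df


def average_term_pvalue(table: pd.DataFrame, protein: str) -> float:
    """avP: the arithmetic mean P-value over ALL term rows of *protein*,
    regardless of term category."""
    rows = table[table["protein_id"] == protein]
    if rows.empty:
        raise KeyError(f"no term rows for protein {protein!r}")
    return float(rows["p_value"].mean())


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient of two equal-length vectors.

    Spearman uses average ranks for ties. Vectors must have length >= 3 and
    be non-constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def mediator_function_correlation(
    table: MediatorTable,
    term_table: pd.DataFrame,
    top: int = 11,
) -> pd.DataFrame:
    """Relate mediation strength to functional importance for the top mediators.

    For the ``top`` strongest mediators (by M^2 total) that have term rows,
    compute avP and return one row per mediator plus the Pearson and Spearman
    coefficients between M^2 and avP as frame attrs ``pearson`` / ``spearman``.
    """
    ranked = rank_mediators(table, top=top)
    rows = []
    for protein, m2 in ranked:
        if (term_table["protein_id"] == protein).any():
            rows.append(
                {
                    "protein": protein,
                    "M2": m2,
                    "avP": average_term_pvalue(term_table, protein),
                }
            )
    out = pd.DataFrame(rows, columns=["protein", "M2", "avP"])
    if len(out) >= 3 and out["M2"].nunique() > 1 and out["avP"].nunique() > 1:
        out.attrs["pearson"] = correlate(out["M2"], out["avP"], "pearson")
        out.attrs["spearman"] = correlate(out["M2"], out["avP"], "spearman")
    return out
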