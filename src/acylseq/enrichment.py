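"""Blank-normalized enrichment, ranking, sequence-logo matrices and
selectivity scores for selection-sequencing screens.

The screen contrasts a selection condition (reads surviving the
periodate-protection selection for a given amino acid and chemistry) with a
blank that went through ligation/RT/PCR only, capturing procedural sequence
bias.  Enrichment of a variant is the ratio of its (pseudocounted)
frequency in the selection sample to its frequency in the blank.  Ranking,
however, follows raw selection read numbers — the blank-normalized ratio is
reported alongside for interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .variant_counting import LibraryDesign, VariantCountTable, enumerate_variants


@dataclass
class EnrichmentTable:
    """Per-variant enrichment statistics for one selection condition.

    ``table`` is indexed by variant (lexicographic order) with columns
    count_sel, count_blank, freq_sel, freq_blank, enrichment,
    log2_enrichment, rank_by_raw_count (1 = most selection reads) and
    percentile (100*rank/4**k; lower = better).
    """

    design: LibraryDesign
    condition_label: str
    pseudocount: float
    table: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="variant")

    def top_variants(self, n: int) -> list[str]:
        ordered = self.table.sort_values("rank_by_raw_count")
        return list(ordered.index[:n])


def compute_enrichment(sel: VariantCountTable, blank: VariantCountTable,
                       pseudocount: float = 1.0,
                       condition_label: str | None = None) -> EnrichmentTable:
    """Pseudocounted frequency ratio of selection over blank, with ranks.

    freq_x(v) = (count_x(v) + a) / sum_w (count_x(w) + a); enrichment is
    freq_sel/freq_blank, always finite and positive thanks to the
    pseudocount a.  Ranks are over raw selection counts, ties broken
    lexicographically by variant so that output is reproducible.
    """
    if sel.design != blank.design:
        raise ValueError("selection and blank tables use different designs")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    variants = enumerate_variants(sel.design.k)
    c_sel = np.array([sel.counts[v] for v in variants], dtype=float)
    c_blank = np.array([blank.counts[v] for v in variants], dtype=float)
    freq_sel = (c_sel + pseudocount) / (c_sel + pseudocount).sum()
    freq_blank = (c_blank + pseudocount) / (c_blank + pseudocount).sum()
    enr = freq_sel / freq_blank

    # stable sort on (-count, variant): lexicographic tie-break for free
    order = sorted(range(len(variants)), key=lambda i: (-c_sel[i], variants[i]))
    rank = np.empty(len(variants), dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r

    df = pd.DataFrame({
        "count_sel": c_sel.astype(int),
        "count_blank": c_blank.astype(int),
        "freq_sel": freq_sel,
        "freq_blank": freq_blank,
        "enrichment": enr,
        "log2_enrichment": np.log2(enr),
        "rank_by_raw_count": rank,
        "percentile": 100.0 * rank / len(variants),
    }, index=pd.Index(variants, name="variant"))
    return EnrichmentTable(design=sel.design,
                           condition_label=condition_label or sel.condition_label,
                           pseudocount=pseudocount, table=df)


def top_fraction(table: EnrichmentTable, fraction: float) -> set[str]:
    """The ceil(fraction * 4**k) variants with the most raw selection reads."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = math.ceil(fraction * table.design.n_variants)
    return set(table.top_variants(n))


def percentile_rank(table: EnrichmentTable, variant: str) -> float:
    """Raw-count percentile of one variant: 100*rank/4**k (lower = better)."""
    if variant not in table.table.index:
        raise KeyError(f"variant {variant!r} not in the design space")
    return float(table.table.loc[variant, "percentile"])


@dataclass
class PositionMatrix:
    """k x 4 base-probability matrix with per-position information content.

    ``probs`` has one row per randomized position and columns A, C, G, U,
    each row summing to 1.  Information content per position is
    IC_j = 2 + sum_b p_j(b) * log2 p_j(b), in [0, 2] bits.
    """

    probs: pd.DataFrame
    information: np.ndarray
    source: str

    def to_tsv(self, path: str | Path) -> None:
        out = self.probs.copy()
        out["IC_bits"] = self.information
        out.to_csv(path, sep="\t", index_label="position")


def _information_content(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=1)


def position_matrix(table: EnrichmentTable, fraction: float = 0.1,
                    weighting: Literal["raw_reads", "uniform"] = "raw_reads",
                    ) -> PositionMatrix:
    """Base-composition matrix of the top-fraction variant set.

    Members of the top set are weighted by their raw selection read counts
    (default, mirroring logos built "from the raw reading numbers") or
    equally.  With raw-read weighting a top set whose counts are all zero
    falls back to uniform weights.
    """
    if weighting not in ("raw_reads", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    top = sorted(top_fraction(table, fraction))
    k = table.design.k
    if weighting == "raw_reads":
        w = table.table.loc[top, "count_sel"].to_numpy(dtype=float)
        if w.sum() == 0:
            w = np.ones(len(top))
    else:
        w = np.ones(len(top))
    w = w / w.sum()
    base_index = {b: i for i, b in enumerate("ACGU")}
    probs = np.zeros((k, 4))
    for variant, weight in zip(top, w):
        for j, b in enumerate(variant):
            probs[j, base_index[b]] += weight
    probs /= probs.sum(axis=1, keepdims=True)
    df = pd.DataFrame(probs, columns=list("ACGU"),
                      index=pd.RangeIndex(k, name="position"))
    return PositionMatrix(probs=df, information=_information_content(probs),
                          source=f"top {fraction:.0%} of {table.condition_label}, "
                                 f"{weighting} weighting")


def condition_correlation(a: VariantCountTable, b: VariantCountTable) -> float:
    """Pearson correlation of raw read-count vectors over the variant space."""
    if a.design != b.design:
        raise ValueError("count tables use different designs")
    variants = enumerate_variants(a.design.k)
    x = np.array([a.counts[v] for v in variants], dtype=float)
    y = np.array([b.counts[v] for v in variants], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a count vector has zero variance")
    return float(stats.pearsonr(x, y).statistic)


def correlation_matrix(tables: Mapping[str, VariantCountTable]) -> pd.DataFrame:
    """Pairwise Pearson correlations between conditions (square DataFrame)."""
    labels = list(tables)
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            r = condition_correlation(tables[la], tables[lb])
            mat.loc[la, lb] = mat.loc[lb, la] = r
    return mat


def selectivity_score(tables: Mapping[str, EnrichmentTable]) -> pd.DataFrame:
    """How idiosyncratically each amino-acid condition prefers each variant.

    score(v, aa) = log2 enrichment_aa(v) - max over aa' != aa of
    log2 enrichment_aa'(v): the log2 margin by which condition ``aa``
    out-enriches its best competitor on variant ``v``.  Positive scores mean
    the variant is preferred by this amino acid over every other; the
    per-condition argmax is the most idiosyncratically preferred variant.

    Returns a variants x conditions DataFrame of scores.
    """
    if len(tables) < 2:
        raise ValueError("selectivity requires >= 2 amino-acid conditions")
    labels = list(tables)
    first = tables[labels[0]]
    for t in tables.values():
        if t.design != first.design:
            raise ValueError("enrichment tables use different designs")
    log2e = pd.DataFrame(
        {aa: tables[aa].table["log2_enrichment"] for aa in labels})
    scores = pd.DataFrame(index=log2e.index, columns=labels, dtype=float)
    arr = log2e.to_numpy()
    for j, aa in enumerate(labels):
        others = np.delete(arr, j, axis=1)
        scores[aa] = arr[:, j] - others.max(axis=1)
    return scores


def top_selectivity(scores: pd.DataFrame, condition: str, n: int = 1) -> list[str]:
    """Top-``n`` variants of one condition by selectivity score (ties lexicographic)."""
    s = scores[condition]
    ordered = sorted(s.index, key=lambda v: (-s[v], v))
    return ordered[:n]
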