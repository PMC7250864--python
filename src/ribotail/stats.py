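"""Downstream statistics on TE calls.

Signal-peptide / transmembrane enrichment among differentially
translated genes (two-sided Fisher's exact test on a 2x2 table built
over the testable background), and codon-usage comparison between two
gene sets (per-codon two-proportion z test with Benjamini-Hochberg
correction across the 61 sense codons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .io import SENSE_CODONS, TranscriptModel

FLAG_MODES = ("signal_peptide", "transmembrane", "either")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment: [[a, b], [c, d]] = membership x annotation."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    degenerate: bool = False


def fisher_two_sided(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test by the point-probability method.

    p is the sum of hypergeometric point probabilities no larger than
    that of the observed table.  The odds ratio is the sample odds
    ratio a*d / (b*c) (inf when only b*c is zero, NaN when both
    products vanish).  A zero row or column margin makes the table
    degenerate: p = 1.
    """
    (a, b), (c, d) = (int(table[0][0]), int(table[0][1])), (int(table[1][0]), int(table[1][1]))
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in contingency table")
    with np.errstate(divide="ignore", invalid="ignore"):
        if b * c == 0:
            odds = np.nan if a * d == 0 else np.inf
        else:
            odds = (a * d) / (b * c)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return EnrichmentResult(((a, b), (c, d)), odds, 1.0, degenerate=True)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(((a, b), (c, d)), float(odds), float(p), degenerate=False)


def _flag_series(transcripts: Sequence[TranscriptModel], mode: str) -> pd.Series:
    if mode not in FLAG_MODES:
        raise ValueError(f"flag mode must be one of {FLAG_MODES}, got {mode!r}")
    idx = pd.Index([t.transcript_id for t in transcripts], name="gene")
    if mode == "signal_peptide":
        vals = [t.has_signal_peptide for t in transcripts]
    elif mode == "transmembrane":
        vals = [t.has_transmembrane for t in transcripts]
    else:
        vals = [t.has_signal_peptide or t.has_transmembrane for t in transcripts]
    return pd.Series(vals, index=idx)


def annotation_enrichment(
    te_records: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    flag_modes: Sequence[str] = FLAG_MODES,
    directions: Sequence[str] = ("down", "up"),
) -> pd.DataFrame:
    """Fisher enrichment of targeting annotations among TE calls.

    For each direction the 2x2 table is {called, not-called} x
    {flagged, unflagged} over the *testable* genes only — genes that
    could not be called cannot inform the enrichment.
    """
    if "call" not in te_records.columns:
        raise ValueError("run call_differential_te before annotation_enrichment")
    testable = te_records[te_records["testable"].astype(bool)].set_index("gene")
    if len(testable) == 0:
        raise ValueError("no testable genes")
    rows = []
    for mode in flag_modes:
        flags = _flag_series(transcripts, mode).reindex(testable.index).fillna(False)
        for direction in directions:
            in_set = testable["call"] == direction
            a = int((in_set & flags).sum())
            b = int((in_set & ~flags).sum())
            c = int((~in_set & flags).sum())
            d = int((~in_set & ~flags).sum())
            res = fisher_two_sided([[a, b], [c, d]])
            rows.append(
                (direction, mode, a, b, c, d, res.odds_ratio, res.p_value, res.degenerate)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "direction",
            "flag",
            "n_called_flagged",
            "n_called_unflagged",
            "n_other_flagged",
            "n_other_unflagged",
            "odds_ratio",
            "p_value",
            "degenerate",
        ],
    )


def _codon_counts(transcripts: Mapping[str, TranscriptModel], genes) -> pd.Series:
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for g in genes:
        for codon in transcripts[g].codons():
            if codon in counts:
                counts[codon] += 1
    return pd.Series(counts)


def codon_usage_compare(
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    set_a,
    set_b,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare sense-codon usage frequencies between two gene sets.

    Frequencies are codon counts over all CDS codons of a set divided
    by the set's total sense-codon count (stop codons excluded).  Each
    codon gets a two-proportion z test; q values are Benjamini-Hochberg
    across the 61 sense codons.
    """
    tidx = (
        transcripts
        if isinstance(transcripts, Mapping)
        else {t.transcript_id: t for t in transcripts}
    )
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    ca = _codon_counts(tidx, set_a)
    cb = _codon_counts(tidx, set_b)
    na, nb = int(ca.sum()), int(cb.sum())
    if na == 0 or nb == 0:
        raise ValueError("a gene set contributes zero codons")
    fa, fb = ca / na, cb / nb

    pvals = np.ones(len(SENSE_CODONS))
    for i, codon in enumerate(SENSE_CODONS):
        if fa[codon] == fb[codon]:
            continue  # includes the 0/0 case; z test is 0 or undefined
        _, p = proportions_ztest([ca[codon], cb[codon]], [na, nb])
        pvals[i] = p if np.isfinite(p) else 1.0
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(fa.to_numpy() / fb.to_numpy())
    out = pd.DataFrame(
        {
            "count_a": ca,
            "count_b": cb,
            "freq_a": fa,
            "freq_b": fb,
            "log2_ratio": log2_ratio,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    out.index.name = "codon"
    return out
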