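"""Ribosome-profiling core: RPF filtering, A-site inference, codon
occupancy, metagene profiles, and translation efficiency.

The A site of a ribosome-protected fragment is inferred at a fixed +15
nt offset from the fragment's 5' end; fragments are kept only if they
are 28-31 nt, uniquely mapped, and their A site falls in the zero
reading frame of the CDS.  Codon occupancy is self-normalised per event
by the basal occupancy — the mean raw occupancy of the three codons
downstream of the A site — so a library with positionally uniform
coverage has occupancy exactly 1 for every codon.  Metagene profiles
rescale each CDS to 50 bins and average per-gene-normalised histograms
with equal gene weight.  Translation efficiency (TE) is RPF CPM over
mRNA CPM (pseudocount 0.5), combined across replicates by geometric
mean, with a 2-fold change calling threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .io import (
    ALIGNMENT_COLUMNS,
    CountTable,
    RpfAlignment,
    SENSE_CODONS,
    TranscriptModel,
    alignments_to_frame,
    transcript_index,
)

A_SITE_OFFSET = 15
RPF_MIN_LENGTH = 28
RPF_MAX_LENGTH = 31


# ---------------------------------------------------------------------------
# filtering and A-site assignment
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    """Filtered alignments plus per-rule rejection counts.

    Rules are applied in order; each read is charged to the first rule
    it fails: unknown_transcript, not_unique, bad_length,
    a_site_outside_cds, out_of_frame.
    """

    alignments: pd.DataFrame
    report: dict[str, int]


def filter_rpfs(
    alignments,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    min_length: int = RPF_MIN_LENGTH,
    max_length: int = RPF_MAX_LENGTH,
    offset: int = A_SITE_OFFSET,
) -> FilterResult:
    """Keep unique 28-31 nt fragments whose A site (5' end + 15) lies in
    the CDS in the zero frame."""
    df = alignments_to_frame(alignments)
    tidx = transcripts if isinstance(transcripts, Mapping) else transcript_index(transcripts)
    cds_start = df["transcript_id"].map({k: t.cds_start for k, t in tidx.items()})
    cds_end = df["transcript_id"].map({k: t.cds_end for k, t in tidx.items()})

    known = cds_start.notna()
    unique = df["is_unique"].astype(bool)
    good_len = df["read_length"].between(min_length, max_length)
    a_site = df["five_prime_pos"] + offset
    in_cds = (a_site >= cds_start) & (a_site < cds_end)
    in_frame = ((a_site - cds_start) % 3) == 0

    report = {"total": int(len(df))}
    keep = known.copy()
    report["unknown_transcript"] = int((~known).sum())
    for name, mask in (
        ("not_unique", unique),
        ("bad_length", good_len),
        ("a_site_outside_cds", in_cds.fillna(False)),
        ("out_of_frame", in_frame.fillna(False)),
    ):
        report[name] = int((keep & ~mask).sum())
        keep &= mask
    report["kept"] = int(keep.sum())
    return FilterResult(alignments=df[keep].reset_index(drop=True), report=report)


@dataclass(frozen=True)
class ASiteAssignment:
    """A single RPF's decoded codon: index within the CDS and identity."""

    transcript_id: str
    codon_index: int
    codon: str
    near_stop: bool  # fewer than 3 CDS codons downstream


def assign_a_site(
    alignment: RpfAlignment, transcript: TranscriptModel, offset: int = A_SITE_OFFSET
) -> ASiteAssignment:
    """A-site codon for one filtered alignment.

    Raises ``ValueError`` when called on a read that would not pass
    :func:`filter_rpfs` (contract violation, not a filter).
    """
    a_site = alignment.five_prime_pos + offset
    if not (transcript.cds_start <= a_site < transcript.cds_end):
        raise ValueError(
            f"{alignment.read_id}: A site {a_site} outside CDS of {transcript.transcript_id}"
        )
    if (a_site - transcript.cds_start) % 3 != 0:
        raise ValueError(f"{alignment.read_id}: A site {a_site} not in frame 0")
    codon_index = (a_site - transcript.cds_start) // 3
    return ASiteAssignment(
        transcript_id=transcript.transcript_id,
        codon_index=codon_index,
        codon=transcript.codon(codon_index),
        near_stop=codon_index >= transcript.n_codons - 3,
    )


def assign_a_sites(
    filtered: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    offset: int = A_SITE_OFFSET,
) -> pd.DataFrame:
    """Vectorised A-site assignment for a filtered alignment table.

    Returns columns read_id, transcript_id, codon_index, codon,
    near_stop.
    """
    tidx = transcripts if isinstance(transcripts, Mapping) else transcript_index(transcripts)
    df = alignments_to_frame(filtered)
    cds_start = df["transcript_id"].map({k: t.cds_start for k, t in tidx.items()})
    n_codons = df["transcript_id"].map({k: t.n_codons for k, t in tidx.items()})
    a_site = df["five_prime_pos"] + offset
    codon_index = ((a_site - cds_start) // 3).astype(int)

    codon = pd.Series("", index=df.index, dtype=object)
    for tid, grp in df.groupby("transcript_id", sort=False):
        t = tidx[str(tid)]
        codon_arr = np.array(t.codons(), dtype=object)
        codon.loc[grp.index] = codon_arr[codon_index.loc[grp.index].to_numpy()]
    return pd.DataFrame(
        {
            "read_id": df["read_id"],
            "transcript_id": df["transcript_id"],
            "codon_index": codon_index,
            "codon": codon,
            "near_stop": (codon_index >= (n_codons - 3)).astype(bool),
        }
    )


# ---------------------------------------------------------------------------
# codon occupancy
# ---------------------------------------------------------------------------


def codon_occupancy(
    assignments: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """Basal-normalised A-site occupancy per sense codon.

    For each A-site event the raw positional count at its codon is
    divided by the basal occupancy of that position — the mean of the
    raw counts at the +1, +2 and +3 downstream codons of the same gene.
    Events with fewer than three downstream CDS codons, or with a zero
    basal, are excluded from the normalisation (counted in
    ``df.attrs``) but still contribute to ``raw_count``.  Per-codon
    normalised occupancy is the mean of the per-event ratios grouped by
    A-site codon identity; codons with no eligible events carry NaN.
    """
    tidx = transcripts if isinstance(transcripts, Mapping) else transcript_index(transcripts)
    raw = {c: 0 for c in SENSE_CODONS}
    num = {c: 0.0 for c in SENSE_CODONS}
    wsum = {c: 0.0 for c in SENSE_CODONS}
    n_near_stop = 0
    n_zero_basal = 0

    if len(assignments) == 0:
        import logging

        logging.getLogger("ribotail").warning("codon_occupancy: empty input")
    for tid, grp in assignments.groupby("transcript_id", sort=False):
        t = tidx[str(tid)]
        n = t.n_codons
        counts = np.bincount(grp["codon_index"].to_numpy(), minlength=n).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(counts)])
        codons = t.codons()
        occupied = np.nonzero(counts)[0]
        for i in occupied:
            c = codons[i]
            evt = counts[i]
            if c in raw:
                raw[c] += int(evt)
            if i > n - 4:
                n_near_stop += int(evt)
                continue
            basal = (csum[i + 4] - csum[i + 1]) / 3.0
            if basal == 0.0:
                n_zero_basal += int(evt)
                continue
            if c in num:
                num[c] += evt * (counts[i] / basal)
                wsum[c] += evt

    out = pd.DataFrame(
        {
            "raw_count": pd.Series(raw),
            "occupancy": pd.Series(
                {c: (num[c] / wsum[c]) if wsum[c] > 0 else np.nan for c in SENSE_CODONS}
            ),
            "n_events_used": pd.Series({c: int(wsum[c]) for c in SENSE_CODONS}),
        }
    )
    out.index.name = "codon"
    out.attrs["n_excluded_near_stop"] = n_near_stop
    out.attrs["n_excluded_zero_basal"] = n_zero_basal
    return out


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Mean per-gene-normalised RPF density over 50 CDS bins."""

    values: np.ndarray
    n_genes: int
    n_bins: int = 50
    n_short_genes: int = 0  # genes with fewer codons than bins (kept, flagged)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": np.arange(self.n_bins), "mean": self.values, "n_genes": self.n_genes}
        )


def metagene_profile(
    assignments: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    gene_set: Iterable[str],
    min_rpf: int = 32,
    n_bins: int = 50,
) -> MetageneProfile:
    """Equal-weight mean of per-gene bin profiles over ``gene_set``.

    Codon positions map to bin floor(n_bins * codon_index / n_codons);
    each gene's binned counts are normalised by its total RPF count
    before averaging.  Genes with fewer than ``min_rpf`` reads are
    dropped; an empty surviving set is an error.
    """
    tidx = transcripts if isinstance(transcripts, Mapping) else transcript_index(transcripts)
    gene_set = set(gene_set)
    profiles = []
    n_short = 0
    sub = assignments[assignments["transcript_id"].isin(gene_set)]
    for tid, grp in sub.groupby("transcript_id", sort=True):
        if len(grp) < min_rpf:
            continue
        t = tidx[str(tid)]
        if t.n_codons < n_bins:
            n_short += 1
        bins = (n_bins * grp["codon_index"].to_numpy()) // t.n_codons
        hist = np.bincount(bins, minlength=n_bins).astype(float)
        profiles.append(hist / hist.sum())
    if not profiles:
        raise ValueError(f"metagene: no gene in the set has >= {min_rpf} RPFs")
    values = np.mean(profiles, axis=0)
    return MetageneProfile(values=values, n_genes=len(profiles), n_bins=n_bins, n_short_genes=n_short)


# ---------------------------------------------------------------------------
# translation efficiency
# ---------------------------------------------------------------------------


def rpf_cds_counts(filtered: pd.DataFrame, transcripts: Sequence[TranscriptModel]) -> pd.Series:
    """Per-transcript counts of filtered (CDS-decoding) RPFs."""
    idx = pd.Index([t.transcript_id for t in transcripts], name="transcript_id")
    counts = filtered.groupby("transcript_id").size()
    return counts.reindex(idx).fillna(0).astype(int)


def compute_te(
    counts: CountTable,
    conditions: tuple[str, str] = ("KO", "CTRL"),
    pseudocount: float = 0.5,
    min_mrna_count: int = 10,
    min_rpf_count: int = 10,
) -> pd.DataFrame:
    """Per-gene translation efficiency and its KO/CTRL log2 ratio.

    A gene is testable when its mRNA count is >= ``min_mrna_count`` in
    every mRNA library and its RPF count is >= ``min_rpf_count`` in at
    least one RPF library.  CPM is computed over testable genes; TE per
    replicate is (rpf_cpm + c) / (mrna_cpm + c) pairing RPF and mRNA
    libraries by (condition, replicate); per-condition TE is the
    geometric mean across replicates.  Non-testable genes carry NaN.
    """
    num_cond, den_cond = conditions
    for cond in conditions:
        if not counts.libraries("rpf", cond) or not counts.libraries("mrna", cond):
            raise ValueError(f"condition {cond!r} lacks an RPF or mRNA library")

    mrna_libs = counts.libraries("mrna")
    rpf_libs = counts.libraries("rpf")
    c = counts.counts
    testable = (c[mrna_libs] >= min_mrna_count).all(axis=1) & (
        c[rpf_libs] >= min_rpf_count
    ).any(axis=1)

    cpm = pd.DataFrame(index=c.index)
    for lib in rpf_libs + mrna_libs:
        total = c.loc[testable, lib].sum()
        cpm[lib] = 1e6 * c[lib] / total if total > 0 else np.nan

    out = pd.DataFrame(index=c.index)
    out.index.name = "gene"
    for lib in rpf_libs:
        out[f"rpf_cpm_{lib.removeprefix('rpf_')}"] = cpm[lib]
    for lib in mrna_libs:
        out[f"mrna_cpm_{lib.removeprefix('mrna_')}"] = cpm[lib]

    design = counts.design
    te_cols = {}
    for cond in conditions:
        reps_rpf = {design.loc[l, "replicate"]: l for l in counts.libraries("rpf", cond)}
        reps_mrna = {design.loc[l, "replicate"]: l for l in counts.libraries("mrna", cond)}
        if set(reps_rpf) != set(reps_mrna):
            raise ValueError(
                f"condition {cond!r}: RPF replicates {sorted(reps_rpf)} do not match "
                f"mRNA replicates {sorted(reps_mrna)}"
            )
        per_rep = [
            (cpm[reps_rpf[r]] + pseudocount) / (cpm[reps_mrna[r]] + pseudocount)
            for r in sorted(reps_rpf)
        ]
        te_cols[cond] = gmean(np.column_stack(per_rep), axis=1)
    for cond in conditions:
        out[f"te_{cond}"] = np.where(testable, te_cols[cond], np.nan)
    out["log2_te_ratio"] = np.log2(out[f"te_{num_cond}"] / out[f"te_{den_cond}"])
    out["testable"] = testable
    return out.reset_index()


def call_differential_te(te_records: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Label genes up/down/unchanged by a fold-change threshold on TE.

    down iff log2_te_ratio <= -log2(threshold); up iff >= +log2;
    non-testable genes propagate as 'not_testable'.
    """
    if threshold <= 1:
        raise ValueError(f"threshold must exceed 1, got {threshold}")
    cut = np.log2(threshold)
    out = te_records.copy()
    lr = out["log2_te_ratio"]
    call = np.select(
        [~out["testable"].astype(bool), lr <= -cut, lr >= cut],
        ["not_testable", "down", "up"],
        default="unchanged",
    )
    out["call"] = call
    return out
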