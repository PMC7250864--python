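"""Synthetic data with known ground truth.

Two generators, mirroring the two experimental arms the pipeline
analyses:

* a ribosome-profiling arm — a synthetic transcriptome whose genes carry
  per-gene translation-efficiency (TE) multipliers between a control and
  a knockout condition, a planted set of translationally down-regulated
  genes, and an elongation stall over the first *k* codons of
  signal-peptide genes in the knockout (a positional density multiplier
  that leaves gene totals untouched, so TE calling and metagene shape
  stay decoupled);
* a cRACE arm — chimeric 3'–5' junction reads for a small non-coding RNA
  whose 3' ends are truncated with a configurable distribution and
  uridylated with probability ``logistic(beta0 + beta1 * truncation)``.

Every generator is a pure function of (config, seed) and emits a truth
table precise enough for exact per-read comparison downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    CountTable,
    SENSE_CODONS,
    STOP_CODONS,
    TranscriptModel,
    build_count_table,
    library_id,
)
from .ribo import A_SITE_OFFSET


class ConfigError(ValueError):
    """Simulation configuration violating its invariants."""


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# ribosome-profiling arm
# ---------------------------------------------------------------------------


@dataclass
class RiboSimConfig:
    """Stated world for the ribosome-profiling simulation.

    Lengths are in codons.  ``te_sigma`` is the natural-log standard
    deviation of the log-normal KO/CTRL TE multiplier of unplanted
    genes; planted genes are set to ``planted_te_ratio`` exactly.
    ``stall_strength`` multiplies RPF density over the first
    ``stall_codons`` codons of signal-peptide genes in the knockout,
    renormalised within the gene so totals reflect TE only.
    """

    n_genes: int = 2000
    cds_length_range: tuple[int, int] = (80, 400)
    utr5_len: int = 20
    utr3_len: int = 20
    fraction_sp_genes: float = 0.25
    fraction_tm_genes: float = 0.10
    mrna_sigma: float = 1.0
    te_sigma: float = 0.15
    n_planted_down: int = 20
    planted_te_ratio: float = 0.4
    sp_down_enrichment: float = 1.0
    stall_strength: float = 5.0
    stall_codons: int = 25
    frame_fidelity: float = 0.9
    unique_fraction: float = 0.95
    library_depth: int = 2_000_000
    read_lengths: tuple[int, ...] = (28, 29, 30, 31)
    read_length_probs: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    n_replicates: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if not (6 <= lo <= hi):
            raise ConfigError(f"infeasible cds_length_range {self.cds_length_range}")
        for name in ("fraction_sp_genes", "fraction_tm_genes", "frame_fidelity", "unique_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.library_depth < 0:
            raise ConfigError("library_depth must be >= 0")
        if self.n_planted_down > self.n_genes:
            raise ConfigError("more planted genes than genes")
        if not 0 < self.planted_te_ratio <= 0.5:
            raise ConfigError("planted_te_ratio must lie in (0, 0.5]")
        if self.stall_strength <= 0 or self.stall_codons < 1:
            raise ConfigError("stall parameters must be positive")
        if len(self.read_lengths) != len(self.read_length_probs):
            raise ConfigError("read length distribution mis-specified")
        if abs(sum(self.read_length_probs) - 1.0) > 1e-9:
            raise ConfigError("read_length_probs must sum to 1")
        # reads at the CDS boundaries must stay on the transcript
        if self.utr5_len < A_SITE_OFFSET + 1:
            raise ConfigError(f"utr5_len must be >= {A_SITE_OFFSET + 1}")
        if self.utr3_len < max(self.read_lengths) - A_SITE_OFFSET + 1:
            raise ConfigError("utr3_len too short for the read-length window")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def generate_transcriptome(
    config: RiboSimConfig, seed
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Random transcriptome plus per-gene truth table.

    CDS = ATG + random sense codons + stop; no internal stop codons, so
    codon-usage statistics see the full sense-codon table.  Exactly
    ``round(fraction * n_genes)`` genes carry each targeting flag.
    The truth table records mRNA abundance, the true KO/CTRL TE ratio,
    the planted-down flag and the stall flag (signal-peptide genes
    stall in the knockout).
    """
    rng = _rng(seed)
    n = config.n_genes
    lo, hi = config.cds_length_range
    n_codons = rng.integers(lo, hi + 1, size=n)

    sense = np.array(SENSE_CODONS)
    stops = np.array(STOP_CODONS)
    transcripts: list[TranscriptModel] = []
    ids = [f"g{i:05d}" for i in range(n)]

    sp = np.zeros(n, dtype=bool)
    sp[rng.choice(n, size=round(config.fraction_sp_genes * n), replace=False)] = True
    tm = np.zeros(n, dtype=bool)
    tm[rng.choice(n, size=round(config.fraction_tm_genes * n), replace=False)] = True

    mrna_abundance = rng.lognormal(0.0, config.mrna_sigma, n)
    te_ratio = rng.lognormal(0.0, config.te_sigma, n)
    weights = np.where(sp, config.sp_down_enrichment, 1.0)
    planted_idx = rng.choice(n, size=config.n_planted_down, replace=False, p=weights / weights.sum())
    planted = np.zeros(n, dtype=bool)
    planted[planted_idx] = True
    te_ratio[planted] = config.planted_te_ratio

    for i in range(n):
        body = sense[rng.integers(0, len(sense), n_codons[i] - 2)]
        cds = "ATG" + "".join(body) + str(stops[rng.integers(0, 3)])
        seq = _random_seq(rng, config.utr5_len) + cds + _random_seq(rng, config.utr3_len)
        transcripts.append(
            TranscriptModel(
                transcript_id=ids[i],
                sequence=seq,
                cds_start=config.utr5_len,
                cds_end=config.utr5_len + 3 * int(n_codons[i]),
                has_signal_peptide=bool(sp[i]),
                has_transmembrane=bool(tm[i]),
            )
        )

    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "n_codons": n_codons,
            "mrna_abundance": mrna_abundance,
            "te_ratio": te_ratio,
            "planted_down": planted,
            "has_signal_peptide": sp,
            "has_transmembrane": tm,
            "stalled": sp,  # stall applies to SP genes in the KO condition
        }
    )
    return transcripts, truth


def simulate_rpf_library(
    transcripts: list[TranscriptModel],
    truth: pd.DataFrame,
    config: RiboSimConfig,
    condition: str,
    seed,
    library: str | None = None,
) -> pd.DataFrame:
    """Draw one RPF library as an alignment table.

    Per-gene read counts are multinomial with weight
    mRNA abundance x TE(condition); within a gene, A-site codons are
    uniform except for the 5'-CDS stall of signal-peptide genes in the
    knockout, where the first ``stall_codons`` codons get
    ``stall_strength``-fold density (renormalised).  The 5' end sits at
    ``cds_start + 3*codon - 15`` plus a +-1 nt frame error with
    probability ``1 - frame_fidelity``.
    """
    if condition not in ("CTRL", "KO"):
        raise ConfigError(f"condition must be CTRL or KO, got {condition!r}")
    rng = _rng(seed)
    library = library or f"rpf_{condition}"
    te = truth["te_ratio"].to_numpy() if condition == "KO" else np.ones(len(truth))
    w = truth["mrna_abundance"].to_numpy() * te
    gene_counts = rng.multinomial(config.library_depth, w / w.sum())

    s, k = config.stall_strength, config.stall_codons
    tid_parts, codon_parts = [], []
    stalled = truth["stalled"].to_numpy() & (condition == "KO") & (s != 1.0)
    n_codons = truth["n_codons"].to_numpy()
    for i, m in enumerate(gene_counts):
        if m == 0:
            continue
        L = int(n_codons[i])
        if stalled[i] and L > k:
            p_head = s * k / (s * k + (L - k))
            in_head = rng.random(m) < p_head
            codons = np.where(
                in_head,
                rng.integers(0, k, m),
                rng.integers(k, L, m),
            )
        else:
            # stall over the whole CDS (L <= k) renormalises to uniform
            codons = rng.integers(0, L, m)
        tid_parts.append(np.full(m, i, dtype=np.int32))
        codon_parts.append(codons.astype(np.int32))

    gene_idx = np.concatenate(tid_parts) if tid_parts else np.empty(0, dtype=np.int32)
    codon_idx = np.concatenate(codon_parts) if codon_parts else np.empty(0, dtype=np.int32)
    n_reads = len(gene_idx)

    cds_start = np.array([t.cds_start for t in transcripts], dtype=np.int32)
    f = config.frame_fidelity
    shift = rng.choice(np.array([-1, 0, 1]), size=n_reads, p=[(1 - f) / 2, f, (1 - f) / 2])
    five_prime = cds_start[gene_idx] + 3 * codon_idx - A_SITE_OFFSET + shift
    lengths = rng.choice(np.array(config.read_lengths), size=n_reads, p=config.read_length_probs)
    unique = rng.random(n_reads) < config.unique_fraction

    tids = pd.Categorical.from_codes(gene_idx, categories=[t.transcript_id for t in transcripts])
    return pd.DataFrame(
        {
            "read_id": [f"{library}:{j}" for j in range(n_reads)],
            "transcript_id": tids.astype(str),
            "five_prime_pos": five_prime.astype(int),
            "read_length": lengths.astype(int),
            "is_unique": unique,
        }
    )


def simulate_mrna_counts(
    truth: pd.DataFrame, config: RiboSimConfig, condition: str, seed
) -> pd.Series:
    """Multinomial mRNA counts; abundances are condition-independent."""
    if condition not in ("CTRL", "KO"):
        raise ConfigError(f"condition must be CTRL or KO, got {condition!r}")
    rng = _rng(seed)
    p = truth["mrna_abundance"].to_numpy()
    counts = rng.multinomial(config.library_depth, p / p.sum())
    return pd.Series(counts, index=pd.Index(truth["transcript_id"], name="transcript_id"))


def simulate_ribo_experiment(
    config: RiboSimConfig, seed
) -> tuple[list[TranscriptModel], pd.DataFrame, dict[str, pd.DataFrame], dict[str, pd.Series]]:
    """Full two-condition experiment: transcriptome, truth, RPF alignment
    tables and mRNA count Series keyed by library id."""
    rng = _rng(seed)
    transcripts, truth = generate_transcriptome(config, rng)
    rpf: dict[str, pd.DataFrame] = {}
    mrna: dict[str, pd.Series] = {}
    for condition in ("CTRL", "KO"):
        for rep in range(1, config.n_replicates + 1):
            lib = library_id("rpf", condition, rep)
            rpf[lib] = simulate_rpf_library(transcripts, truth, config, condition, rng, library=lib)
            mrna[library_id("mrna", condition, rep)] = simulate_mrna_counts(
                truth, config, condition, rng
            )
    return transcripts, truth, rpf, mrna


# ---------------------------------------------------------------------------
# cRACE arm
# ---------------------------------------------------------------------------


@dataclass
class CraceSimConfig:
    """Stated world for the cRACE junction-read simulation.

    3' termini: canonical with probability ``p_canonical``, genomically
    extended (1..``max_extension`` nt into a Pol III terminator-like
    downstream sequence beginning with TTTT) with probability
    ``p_extension``, otherwise truncated by a geometric number of
    nucleotides.  Uridylation probability follows
    ``logistic(beta0 + beta1 * x)`` with x = truncation in nt
    (genomic extension enters as negative truncation).  Uridylated tails
    are 5 + Poisson(``tail_mean_extra``) uridines; non-uridylated reads
    carry a sub-threshold 1-4 U tail with probability
    ``short_tail_prob``.
    """

    reference_length: int = 300
    extension_length: int = 20
    five_prime_anchor_len: int = 30
    three_prime_seg_len: int = 50
    p_canonical: float = 0.15
    p_extension: float = 0.10
    max_extension: int = 4
    truncation_geom_p: float = 0.08
    max_truncation: int = 150
    beta0: float = -3.0
    beta1: float = 0.25
    tail_mean_extra: float = 2.0
    short_tail_prob: float = 0.10
    n_reads: int = 1000
    substitution_rate: float = 0.0
    min_anchor: int = 12

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta1):
            raise ConfigError("beta1 must be finite")
        if self.p_canonical + self.p_extension > 1.0:
            raise ConfigError("p_canonical + p_extension > 1")
        if self.five_prime_anchor_len < self.min_anchor:
            raise ConfigError(
                f"five_prime_anchor_len < junction-detection minimum ({self.min_anchor})"
            )
        if self.three_prime_seg_len < self.min_anchor:
            raise ConfigError("three_prime_seg_len below junction-detection minimum")
        if not 1 <= self.max_extension <= self.extension_length:
            raise ConfigError("max_extension outside genomic extension")
        if self.max_truncation + self.three_prime_seg_len > self.reference_length - self.five_prime_anchor_len:
            raise ConfigError(
                "max_truncation too deep: 3' segments would overlap the 5' anchor region"
            )
        if not 0 < self.truncation_geom_p <= 1:
            raise ConfigError("truncation_geom_p outside (0, 1]")


def make_crace_reference(config: CraceSimConfig, seed):
    """Random mature reference plus a TTTT-initial genomic extension."""
    from .crace import CraceReference

    rng = _rng(seed)
    mature = _random_seq(rng, config.reference_length)
    extension = "TTTT" + _random_seq(rng, config.extension_length - 4)
    return CraceReference(
        mature_seq=mature,
        genomic_extension=extension,
        five_prime_anchor_len=config.five_prime_anchor_len,
    )


def _canonical_call(reference, end_pos: int, tail: str) -> tuple[int, str]:
    """Greedy templated-first normal form of a constructed 3' end.

    Moves tail nucleotides that continue the template (mature sequence,
    then the genomic extension) into the templated segment, exactly as a
    caller applying the templated-first rule must.  Returns the
    canonical (end_offset, tail).
    """
    mature, ext = reference.mature_seq, reference.genomic_extension
    ce = reference.canonical_end
    pos = end_pos
    i = 0
    while i < len(tail):
        nxt = mature[pos] if pos < ce else (ext[pos - ce] if pos - ce < len(ext) else None)
        if nxt is None or tail[i] != nxt:
            break
        pos += 1
        i += 1
    return pos - ce, tail[i:]


def simulate_crace_reads(
    reference, config: CraceSimConfig, seed
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate chimeric cRACE reads plus an exact per-read truth table.

    Each read is ``templated 3' segment (ending at the sampled terminus)
    + non-templated tail + 5' anchor``.  The truth table stores the
    *canonical* end offset and tail (greedy templated-first normal
    form), i.e. exactly what a correct caller must report, alongside the
    generative truncation and uridylation draw.
    """
    rng = _rng(seed)
    mature, ext = reference.mature_seq, reference.genomic_extension
    ce = reference.canonical_end
    seg_len = config.three_prime_seg_len
    anchor = mature[: reference.five_prime_anchor_len]

    u = rng.random(config.n_reads)
    offsets = np.empty(config.n_reads, dtype=int)
    canonical = u < config.p_canonical
    extended = (~canonical) & (u < config.p_canonical + config.p_extension)
    offsets[canonical] = 0
    offsets[extended] = rng.integers(1, config.max_extension + 1, int(extended.sum()))
    n_trunc = int((~canonical & ~extended).sum())
    trunc = rng.geometric(config.truncation_geom_p, n_trunc)
    offsets[~canonical & ~extended] = -np.minimum(trunc, config.max_truncation)

    x = -offsets.astype(float)  # truncation in nt; extension negative
    urid = rng.random(config.n_reads) < expit(config.beta0 + config.beta1 * x)
    tail_len = np.where(
        urid,
        5 + rng.poisson(config.tail_mean_extra, config.n_reads),
        np.where(
            rng.random(config.n_reads) < config.short_tail_prob,
            rng.integers(1, 5, config.n_reads),
            0,
        ),
    )

    reads: list[tuple[str, str]] = []
    rows = []
    bases = np.array(list("ACGT"))
    for j in range(config.n_reads):
        off = int(offsets[j])
        end_pos = ce + off
        if off <= 0:
            seg = mature[end_pos - seg_len : end_pos]
        else:
            seg = mature[ce - (seg_len - off) : ce] + ext[:off]
        tail = "T" * int(tail_len[j])
        seq = seg + tail + anchor
        if config.substitution_rate > 0:
            arr = np.array(list(seq))
            hit = rng.random(len(arr)) < config.substitution_rate
            arr[hit] = bases[rng.integers(0, 4, int(hit.sum()))]
            seq = "".join(arr)
        read_id = f"crace:{j}"
        reads.append((read_id, seq))
        canon_off, canon_tail = _canonical_call(reference, end_pos, tail)
        from .io import rna

        rows.append(
            (
                read_id,
                canon_off,
                rna(canon_tail),
                "UUUUU" in rna(canon_tail),
                off,
                bool(urid[j]),
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "end_offset",
            "tail_seq",
            "is_uridylated",
            "sim_offset",
            "sim_uridylated",
        ],
    )
    return reads, truth


def simulate_logistic_dataset(config: CraceSimConfig, seed) -> pd.DataFrame:
    """Draw (truncation, uridylated) pairs straight from the generative
    logistic model — the parameter-recovery benchmark for the fitter,
    free of tail-calling reassignment effects."""
    rng = _rng(seed)
    u = rng.random(config.n_reads)
    offsets = np.empty(config.n_reads, dtype=int)
    canonical = u < config.p_canonical
    extended = (~canonical) & (u < config.p_canonical + config.p_extension)
    offsets[canonical] = 0
    offsets[extended] = rng.integers(1, config.max_extension + 1, int(extended.sum()))
    n_trunc = int((~canonical & ~extended).sum())
    offsets[~canonical & ~extended] = -np.minimum(
        rng.geometric(config.truncation_geom_p, n_trunc), config.max_truncation
    )
    x = -offsets.astype(float)
    y = rng.random(config.n_reads) < expit(config.beta0 + config.beta1 * x)
    return pd.DataFrame(
        {
            "read_id": [f"sim:{j}" for j in range(config.n_reads)],
            "end_offset": offsets,
            "is_uridylated": y,
            "junction_found": True,
        }
    )
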