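"""On-disk formats and core record types.

Everything the pipeline reads or writes passes through this module:
transcript FASTA, the transcript annotation table (CDS coordinates plus
signal-peptide / transmembrane flags), ribosome-protected-fragment (RPF)
alignments in transcript space (TSV or SAM), count tables and result
tables, and the JSON run manifest.

Coordinate conventions: 0-based, half-open everywhere in memory.  SAM
ingestion converts from 1-based POS at the boundary.  Sequences are
stored DNA-style (U normalised to T); U appears only in human-readable
tail reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("ribotail")

SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")


class FastaParseError(ValueError):
    """Malformed FASTA input (empty record, header problems)."""


class AnnotationError(ValueError):
    """Transcript annotation violating the CDS model invariants."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse the RNA/DNA alphabet onto DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    """Render a DNA-internal sequence in the RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript sequence with its CDS interval and targeting flags.

    ``cds_start``/``cds_end`` are 0-based half-open transcript
    coordinates.  The CDS must be a whole number of codons and at least
    six codons long (start + four sense + stop is the smallest gene we
    accept).
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int
    has_signal_peptide: bool = False
    has_transmembrane: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.transcript_id:
            raise AnnotationError("empty transcript_id")
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )
        if self.n_codons < 6:
            raise AnnotationError(
                f"{self.transcript_id}: CDS of {self.n_codons} codons; minimum is 6"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    def codon(self, codon_index: int) -> str:
        if not 0 <= codon_index < self.n_codons:
            raise IndexError(
                f"{self.transcript_id}: codon index {codon_index} outside CDS "
                f"of {self.n_codons} codons"
            )
        start = self.cds_start + 3 * codon_index
        return self.sequence[start : start + 3]

    def codons(self) -> list[str]:
        cds = self.cds_sequence
        return [cds[i : i + 3] for i in range(0, len(cds), 3)]


class RpfAlignment(NamedTuple):
    """One RPF read placed on a transcript (5' end, 0-based)."""

    read_id: str
    transcript_id: str
    five_prime_pos: int
    read_length: int
    is_unique: bool


ALIGNMENT_COLUMNS = ["read_id", "transcript_id", "five_prime_pos", "read_length", "is_unique"]


def alignments_to_frame(alignments) -> pd.DataFrame:
    """Normalise a list of :class:`RpfAlignment` (or a frame) to a DataFrame."""
    if isinstance(alignments, pd.DataFrame):
        missing = [c for c in ALIGNMENT_COLUMNS if c not in alignments.columns]
        if missing:
            raise ValueError(f"alignment table missing columns: {missing}")
        return alignments
    return pd.DataFrame(list(alignments), columns=ALIGNMENT_COLUMNS)


def frame_to_alignments(df: pd.DataFrame) -> list[RpfAlignment]:
    return [
        RpfAlignment(str(r), str(t), int(p), int(n), bool(u))
        for r, t, p, n, u in df[ALIGNMENT_COLUMNS].itertuples(index=False)
    ]


@dataclass
class CountTable:
    """Per-transcript read counts across sequencing libraries.

    ``counts`` is indexed by transcript_id with one column per
    library_id; ``design`` maps each library_id to its kind
    ('rpf' or 'mrna'), condition, and replicate number.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        design = self.design
        for col in ("kind", "condition", "replicate"):
            if col not in design.columns:
                raise ValueError(f"design table missing column {col!r}")
        unknown = set(self.counts.columns) - set(design.index)
        if unknown:
            raise ValueError(f"libraries missing from design: {sorted(unknown)}")
        bad_kind = set(design["kind"]) - {"rpf", "mrna"}
        if bad_kind:
            raise ValueError(f"unknown library kinds: {sorted(bad_kind)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def libraries(self, kind: str | None = None, condition: str | None = None) -> list[str]:
        design = self.design.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=design.index)
        if kind is not None:
            mask &= design["kind"] == kind
        if condition is not None:
            mask &= design["condition"] == condition
        return list(design.index[mask])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.design["condition"].unique())


def library_id(kind: str, condition: str, replicate: int) -> str:
    return f"{kind}_{condition}_rep{replicate}"


def design_from_library_ids(library_ids: Iterable[str]) -> pd.DataFrame:
    """Recover the design table from ``{kind}_{condition}_rep{n}`` ids."""
    rows = []
    for lib in library_ids:
        try:
            kind, condition, rep = lib.split("_")
            if not rep.startswith("rep"):
                raise ValueError
            rows.append((lib, kind, condition, int(rep[3:])))
        except ValueError as exc:
            raise ValueError(
                f"library id {lib!r} not of the form kind_condition_repN"
            ) from exc
    return pd.DataFrame(
        rows, columns=["library_id", "kind", "condition", "replicate"]
    ).set_index("library_id")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased with U normalised to T; record order is
    preserved.  Structural problems (empty record, stray sequence lines)
    raise :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    # validation pass with line numbers (Bio.SeqIO silently tolerates
    # empty records, which we must reject)
    header_line: int | None = None
    n_seq = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and n_seq == 0:
                    raise FastaParseError(f"{path}:{header_line}: record with empty sequence")
                if stripped == ">":
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                n_seq = 0
            else:
                if header_line is None:
                    raise FastaParseError(f"{path}:{lineno}: sequence before first header")
                n_seq += len(stripped)
    if header_line is None:
        raise FastaParseError(f"{path}: no FASTA records")
    if n_seq == 0:
        raise FastaParseError(f"{path}:{header_line}: record with empty sequence")
    return [(rec.id, normalize_sequence(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


ANNOTATION_COLUMNS = [
    "transcript_id",
    "cds_start",
    "cds_end",
    "has_signal_peptide",
    "has_transmembrane",
]

_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise AnnotationError(f"cannot parse boolean flag from {value!r}")


def read_annotation(path: str | Path, fasta: Sequence[tuple[str, str]]) -> list[TranscriptModel]:
    """Join the annotation TSV with FASTA sequences into TranscriptModels.

    Every invariant violation is collected and reported per record; a
    single :class:`AnnotationError` summarising all failures is raised.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    seqs = dict(fasta)
    models: list[TranscriptModel] = []
    errors: list[str] = []
    for row in df.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            errors.append(f"{tid}: no sequence in FASTA")
            continue
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    sequence=seqs[tid],
                    cds_start=int(row.cds_start),
                    cds_end=int(row.cds_end),
                    has_signal_peptide=_parse_bool(row.has_signal_peptide),
                    has_transmembrane=_parse_bool(row.has_transmembrane),
                )
            )
        except (AnnotationError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise AnnotationError(
            f"{path}: {len(errors)} invalid annotation record(s):\n" + "\n".join(errors)
        )
    return models


def write_annotation(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (t.transcript_id, t.cds_start, t.cds_end, t.has_signal_peptide, t.has_transmembrane)
            for t in transcripts
        ],
        columns=ANNOTATION_COLUMNS,
    )
    write_table(df, path)


def transcript_index(transcripts: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {t.transcript_id: t for t in transcripts}


def read_alignments(
    path: str | Path,
    format: str = "tsv",
    transcripts: Mapping[str, TranscriptModel] | None = None,
) -> pd.DataFrame:
    """Read RPF alignments from TSV or transcript-space SAM.

    Multimappers are retained with ``is_unique=False`` (filtering is the
    job of :mod:`ribotail.ribo`).  SAM ingestion keeps forward-strand
    primary mapped records only, converting 1-based POS to a 0-based
    five_prime_pos; uniqueness comes from the NH tag when present.
    Records whose coordinates fall outside the transcript are dropped
    with a logged count (also in ``df.attrs['n_skipped']``).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        df = df[ALIGNMENT_COLUMNS].copy()
        df["is_unique"] = df["is_unique"].map(_parse_bool)
    elif format == "sam":
        rows = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_reverse:
                    continue
                length = rec.query_length or rec.infer_read_length() or 0
                unique = (not rec.has_tag("NH")) or rec.get_tag("NH") == 1
                rows.append(
                    (rec.query_name, rec.reference_name, rec.reference_start, length, unique)
                )
        df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    else:
        raise ValueError(f"unknown alignment format {format!r} (expected 'tsv' or 'sam')")

    df["five_prime_pos"] = df["five_prime_pos"].astype(int)
    df["read_length"] = df["read_length"].astype(int)
    n_skipped = 0
    bad = (df["five_prime_pos"] < 0) | (df["read_length"] <= 0)
    if transcripts is not None:
        tlen = df["transcript_id"].map(
            {tid: t.length for tid, t in transcripts.items()}
        )
        bad |= tlen.isna() | (df["five_prime_pos"] + df["read_length"] > tlen.fillna(0))
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("%s: skipped %d alignment record(s) with invalid coordinates", path, n_skipped)
        df = df[~bad].reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    return df


def write_alignments(df: pd.DataFrame, path: str | Path) -> None:
    write_table(alignments_to_frame(df)[ALIGNMENT_COLUMNS], path)


# ---------------------------------------------------------------------------
# tables, counts, manifest
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with deterministic column order and float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Counts as TSV; the design round-trips through the library ids."""
    df = table.counts.copy()
    df.insert(0, "transcript_id", df.index)
    write_table(df, path)


def read_count_table(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t").set_index("transcript_id")
    df = df.astype(int)
    return CountTable(counts=df, design=design_from_library_ids(df.columns))


def build_count_table(
    rpf_counts: Mapping[str, pd.Series],
    mrna_counts: Mapping[str, pd.Series],
    transcripts: Sequence[TranscriptModel],
) -> CountTable:
    """Assemble a CountTable from per-library count Series.

    Library ids must follow the ``{kind}_{condition}_rep{n}`` scheme.
    Transcripts absent from a Series get count 0.
    """
    index = pd.Index([t.transcript_id for t in transcripts], name="transcript_id")
    cols = {}
    for lib, series in {**rpf_counts, **mrna_counts}.items():
        cols[lib] = series.reindex(index).fillna(0).astype(int)
    counts = pd.DataFrame(cols, index=index)
    return CountTable(counts=counts, design=design_from_library_ids(counts.columns))


def write_manifest(path: str | Path, *, config: Mapping, seed: int | None, inputs: Mapping | None = None) -> None:
    """Record everything needed to reproduce a run byte-for-byte."""
    from . import __version__

    manifest = {
        "tool": "ribotail",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "inputs": _jsonable(inputs or {}),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
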