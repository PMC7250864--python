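"""cRACE 3'-end reconstruction and uridylation-tail modelling.

Circularisation RACE ligates an RNA's 3' end to its own 5' end;
divergent PCR then yields chimeric reads of the form

    [3'-terminal segment][non-templated tail][5'-end anchor]

so the exact 3' terminus and any post-transcriptional tail sit at an
internal junction.  This module locates that junction, partitions tail
nucleotides into templated (continuing the mature sequence or its
downstream genomic extension — for Pol III transcripts typically a
TTTT terminator) and non-templated, calls a read uridylated when the
non-templated tail contains at least five consecutive uridines
(which separates genuine U tails from genomically extended species
carrying four templated U's), and fits a logistic model for the
probability of uridylation as a function of 3' truncation depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .io import normalize_sequence, rna

MIN_ANCHOR_DEFAULT = 12


@dataclass(frozen=True)
class CraceReference:
    """Mature RNA sequence plus its downstream genomic context.

    The canonical 3' end is the end of ``mature_seq``; offsets are
    reported relative to it (negative = truncated, positive =
    genomically extended).  ``five_prime_anchor_len`` is the length of
    the 5' prefix used to locate the circularisation junction.
    """

    mature_seq: str
    genomic_extension: str
    five_prime_anchor_len: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", normalize_sequence(self.mature_seq))
        object.__setattr__(
            self, "genomic_extension", normalize_sequence(self.genomic_extension)
        )
        if not self.mature_seq:
            raise ValueError("empty mature sequence")
        if not self.genomic_extension:
            raise ValueError("empty genomic extension")
        if not 0 < self.five_prime_anchor_len <= len(self.mature_seq):
            raise ValueError("five_prime_anchor_len outside mature sequence")

    @property
    def canonical_end(self) -> int:
        return len(self.mature_seq)

    @property
    def anchor(self) -> str:
        return self.mature_seq[: self.five_prime_anchor_len]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CraceReference":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            mature_seq=data["mature_seq"],
            genomic_extension=data["genomic_extension"],
            five_prime_anchor_len=int(data.get("five_prime_anchor_len", 30)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "mature_seq": self.mature_seq,
                    "genomic_extension": self.genomic_extension,
                    "five_prime_anchor_len": self.five_prime_anchor_len,
                },
                fh,
                sort_keys=True,
            )


@dataclass(frozen=True)
class Junction:
    """Coordinates of the 3'-5' junction within a read.

    ``end_in_read`` — position just past the mature-templated 3'
    terminus; ``five_prime_start_in_read`` — where the 5' anchor begins;
    ``ref_end_pos`` — the terminus in mature coordinates.  ``reason``
    explains a failed search (no_anchor_pair, ambiguous,
    short_3prime_match).
    """

    found: bool
    end_in_read: int = -1
    five_prime_start_in_read: int = -1
    ref_end_pos: int = -1
    reason: str = ""


def _occurrences(needle: str, haystack: str, max_mismatches: int = 0) -> list[int]:
    if max_mismatches == 0:
        out, start = [], 0
        while True:
            i = haystack.find(needle, start)
            if i < 0:
                return out
            out.append(i)
            start = i + 1  # overlapping occurrences count
    out = []
    for i in range(len(haystack) - len(needle) + 1):
        mism = 0
        for a, b in zip(needle, haystack[i : i + len(needle)]):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        if mism <= max_mismatches:
            out.append(i)
    return out


def locate_junction(
    read: str,
    reference: CraceReference,
    min_anchor: int = MIN_ANCHOR_DEFAULT,
    max_anchor_mismatches: int = 0,
) -> Junction:
    """Find the circularisation junction in a chimeric read.

    The 5' anchor (the reference's first ``five_prime_anchor_len`` nt)
    must occur exactly once in the read; the segment before it holds
    the 3' terminus plus any tail.  The terminus is placed by the
    longest prefix of that segment matching contiguously (and
    uniquely) inside the mature sequence; matches shorter than
    ``min_anchor`` are rejected.  Anchor matching is exact by default;
    ``max_anchor_mismatches=1`` tolerates one substitution in the
    anchor (ambiguity still discards the read).
    """
    read = normalize_sequence(read)
    if len(read) < 2 * min_anchor:
        return Junction(found=False, reason="read_too_short")
    hits = _occurrences(reference.anchor, read, max_anchor_mismatches)
    if len(hits) == 0:
        return Junction(found=False, reason="no_anchor_pair")
    if len(hits) > 1:
        return Junction(found=False, reason="ambiguous")
    anchor_start = hits[0]
    seg = read[:anchor_start]
    if len(seg) < min_anchor:
        return Junction(found=False, reason="short_3prime_match")

    # longest prefix of seg that occurs in the mature sequence
    best_k, best_hits = 0, []
    k = min_anchor
    hits_k = _occurrences(seg[:k], reference.mature_seq)
    while hits_k and k <= len(seg):
        best_k, best_hits = k, hits_k
        k += 1
        if k > len(seg):
            break
        hits_k = [i for i in hits_k if reference.mature_seq[i : i + k] == seg[:k]]
    if best_k < min_anchor or not best_hits:
        return Junction(found=False, reason="short_3prime_match")
    if len(best_hits) > 1:
        return Junction(found=False, reason="ambiguous")
    return Junction(
        found=True,
        end_in_read=best_k,
        five_prime_start_in_read=anchor_start,
        ref_end_pos=best_hits[0] + best_k,
    )


@dataclass(frozen=True)
class TailCall:
    """One read's reconstructed 3' end.

    ``end_offset`` is signed nt relative to the canonical 3' end
    (negative = truncated, positive = genomically extended);
    ``tail_seq`` is the non-templated 3' addition in the RNA alphabet;
    ``is_uridylated`` applies the >=5 consecutive U rule to the
    non-templated tail, ``is_uridylated_raw`` to the raw read segment
    past the mature-matched terminus (templated U's included) for
    comparison with the literal read-level rule.
    """

    read_id: str
    end_offset: int = 0
    tail_seq: str = ""
    is_uridylated: bool = False
    is_uridylated_raw: bool = False
    junction_found: bool = True
    reason: str = ""


URIDYLATION_RUN = 5


def call_tail(
    read_id: str,
    read: str,
    reference: CraceReference,
    min_anchor: int = MIN_ANCHOR_DEFAULT,
    max_anchor_mismatches: int = 0,
) -> TailCall:
    """Partition a junction read into templated 3' end and tail.

    Starting at the mature-matched terminus, nucleotides are consumed
    greedily while they continue the template — first the mature
    sequence, then the genomic extension when the canonical end is
    crossed.  Whatever remains before the 5' anchor is the
    non-templated tail.  The greedy templated-first rule makes
    uridylation calls conservative: a genomically extended species
    ending in the templated TTTT is never called uridylated.
    """
    read = normalize_sequence(read)
    junction = locate_junction(
        read, reference, min_anchor=min_anchor, max_anchor_mismatches=max_anchor_mismatches
    )
    if not junction.found:
        return TailCall(read_id=read_id, junction_found=False, reason=junction.reason)
    mature, ext = reference.mature_seq, reference.genomic_extension
    ce = reference.canonical_end
    pos = junction.ref_end_pos
    i = junction.end_in_read
    raw_segment = read[i : junction.five_prime_start_in_read]
    while i < junction.five_prime_start_in_read:
        nxt = mature[pos] if pos < ce else (ext[pos - ce] if pos - ce < len(ext) else None)
        if nxt is None or read[i] != nxt:
            break
        pos += 1
        i += 1
    tail = rna(read[i : junction.five_prime_start_in_read])
    return TailCall(
        read_id=read_id,
        end_offset=pos - ce,
        tail_seq=tail,
        is_uridylated="U" * URIDYLATION_RUN in tail,
        is_uridylated_raw="U" * URIDYLATION_RUN in rna(raw_segment),
        junction_found=True,
    )


def call_tails(
    reads: Iterable[tuple[str, str]],
    reference: CraceReference,
    min_anchor: int = MIN_ANCHOR_DEFAULT,
    max_anchor_mismatches: int = 0,
) -> pd.DataFrame:
    """Tail calls for a read set, as a DataFrame (one row per read)."""
    calls = [
        call_tail(rid, seq, reference, min_anchor=min_anchor,
                  max_anchor_mismatches=max_anchor_mismatches)
        for rid, seq in reads
    ]
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "end_offset": [c.end_offset for c in calls],
            "tail_seq": [c.tail_seq for c in calls],
            "is_uridylated": [c.is_uridylated for c in calls],
            "is_uridylated_raw": [c.is_uridylated_raw for c in calls],
            "junction_found": [c.junction_found for c in calls],
            "reason": [c.reason for c in calls],
        }
    )


def tail_spectrum(tail_calls: pd.DataFrame) -> pd.DataFrame:
    """Read counts and uridylated fraction per 3'-end offset."""
    ok = tail_calls[tail_calls["junction_found"].astype(bool)]
    if len(ok) == 0:
        raise ValueError("no successful tail calls")
    grouped = ok.groupby("end_offset")["is_uridylated"]
    out = pd.DataFrame(
        {
            "n_reads": grouped.size(),
            "n_uridylated": grouped.sum().astype(int),
        }
    ).reset_index()
    out["frac_uridylated"] = out["n_uridylated"] / out["n_reads"]
    out.attrs["overall_frac_uridylated"] = float(ok["is_uridylated"].mean())
    return out


# ---------------------------------------------------------------------------
# logistic model of uridylation vs truncation
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """Maximum-likelihood logit fit P(uridylated) = s(b0 + b1 * x).

    x is the 3' truncation in nt (x = -end_offset; genomic extension
    enters as negative truncation).  Standard errors come from the
    observed information at the optimum.  Complete or quasi-complete
    separation is detected up front and flagged; the coefficients are
    then reported as unbounded rather than iterated to overflow.
    """

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    loglik: float
    n: int
    n_iter: int
    converged: bool
    separation_flag: bool

    def predict(self, x) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))

    def wald(self) -> tuple[float, float]:
        """Wald z and two-sided p for H0: beta1 = 0."""
        from scipy.stats import norm

        if not np.isfinite(self.beta1) or not np.isfinite(self.se_beta1) or self.se_beta1 == 0:
            return np.nan, np.nan
        z = self.beta1 / self.se_beta1
        return float(z), float(2 * norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "se_beta0": self.se_beta0,
            "se_beta1": self.se_beta1,
            "loglik": self.loglik,
            "n": self.n,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
        }


def _log_likelihood(x: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = beta[0] + beta[1] * x
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete or quasi-complete separation along the single predictor."""
    x0, x1 = x[y == 0], x[y == 1]
    return bool(x0.max() <= x1.min() or x1.max() <= x0.min())


def fit_logistic_xy(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticModel:
    """Newton-Raphson ML fit of a one-predictor logistic regression.

    Converges when the score (gradient) norm drops below ``tol``; steps
    are halved when a full Newton step lowers the log-likelihood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary")
    if y.min() == y.max():
        raise ValueError("both outcomes must be present")
    if _separated(x, y):
        sign = 1.0 if np.mean(x[y == 1]) >= np.mean(x[y == 0]) else -1.0
        return LogisticModel(
            beta0=-sign * np.inf,
            beta1=sign * np.inf,
            se_beta0=np.inf,
            se_beta1=np.inf,
            loglik=np.nan,
            n=len(y),
            n_iter=0,
            converged=False,
            separation_flag=True,
        )

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _log_likelihood(x, y, beta)
    converged = False
    n_iter = 0
    H = np.eye(2)
    for n_iter in range(1, max_iter + 1):
        mu = expit(X @ beta)
        g = X.T @ (y - mu)
        if np.linalg.norm(g) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # step halving guards rare overshoots
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_cand = _log_likelihood(x, y, cand)
            if ll_cand >= ll - 1e-12:
                beta, ll = cand, ll_cand
                break
            factor /= 2.0
        else:
            break
    mu = expit(X @ beta)
    if np.linalg.norm(X.T @ (y - mu)) < tol:
        converged = True
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return LogisticModel(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        loglik=_log_likelihood(x, y, beta),
        n=len(y),
        n_iter=n_iter,
        converged=converged,
        separation_flag=False,
    )


def fit_uridylation_logistic(
    tail_calls: pd.DataFrame,
    include_extended: bool = True,
    min_calls: int = 10,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticModel:
    """Fit P(uridylated) against 3' truncation depth from tail calls.

    The predictor is truncation in nt, x = -end_offset, one signed axis
    on which genomic extensions appear as negative truncation; set
    ``include_extended=False`` to restrict the fit to non-extended
    reads (end_offset <= 0).
    """
    ok = tail_calls[tail_calls["junction_found"].astype(bool)]
    if not include_extended:
        ok = ok[ok["end_offset"] <= 0]
    if len(ok) < min_calls:
        raise ValueError(f"need >= {min_calls} successful calls, have {len(ok)}")
    x = -ok["end_offset"].to_numpy(dtype=float)
    y = ok["is_uridylated"].to_numpy(dtype=float)
    return fit_logistic_xy(x, y, tol=tol, max_iter=max_iter)
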