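"""DNA sequence and numeric-series I/O plus synthetic generators.

Reading and writing FASTA goes through Bio.SeqIO; numeric series travel as
two-column CSV (index, value).  The synthetic generators produce (a) random
DNA under an i.i.d. or first-order Markov base model and (b) ARFIMA(p, d, q)
series with known parameters, so every downstream module can be exercised
without downloading genomes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL = "ACGT"
# IUPAC ambiguity codes and the canonical bases each may stand for.
IUPAC_AMBIGUITY = {
    "N": "ACGT", "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


class FastaFormatError(ValueError):
    """Malformed FASTA structure (e.g. record without a header)."""


class SequenceContentError(ValueError):
    """A residue outside the canonical + IUPAC alphabet, with its position."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated nucleotide string with an identifier.

    ``bases`` holds only canonical uppercase A/C/G/T after construction.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases) - set(CANONICAL)
        if bad:
            pos = next(i for i, b in enumerate(self.bases) if b in bad)
            raise SequenceContentError(
                f"non-canonical residue {self.bases[pos]!r} at position {pos + 1} "
                f"in sequence {self.id!r}"
            )

    @property
    def n(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification for a synthetic DNA sequence.

    model 'uniform' draws i.i.d. bases from ``base_probs`` (length-4 vector in
    A, C, G, T order); model 'markov1' uses a 4x4 row-stochastic transition
    matrix whose stationary distribution seeds the first base.
    """

    length: int
    model: Literal["uniform", "markov1"] = "uniform"
    base_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        probs = np.asarray(self.base_probs, dtype=float)
        if self.model == "uniform":
            if probs.shape != (4,):
                raise ValueError("uniform model needs a 4-vector of base probabilities")
            rows = probs[None, :]
        elif self.model == "markov1":
            if probs.shape != (4, 4):
                raise ValueError("markov1 model needs a 4x4 transition matrix")
            rows = probs
        else:
            raise ValueError(f"unknown model {self.model!r}")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("probability rows must sum to 1 within 1e-12")
        if (rows < 0).any():
            raise ValueError("probabilities must be non-negative")


def _canonicalize(raw: str, seq_id: str, *, ambiguity: str, rng: np.random.Generator) -> str:
    """Uppercase and resolve ambiguity codes per policy ('random' or 'strict')."""
    up = raw.upper()
    out = []
    for i, b in enumerate(up):
        if b in CANONICAL:
            out.append(b)
        elif b in IUPAC_AMBIGUITY:
            if ambiguity == "strict":
                raise SequenceContentError(
                    f"ambiguity code {b!r} at position {i + 1} in sequence "
                    f"{seq_id!r} (strict mode)"
                )
            choices = IUPAC_AMBIGUITY[b]
            out.append(choices[rng.integers(len(choices))])
        else:
            raise SequenceContentError(
                f"invalid residue {b!r} at position {i + 1} in sequence {seq_id!r}"
            )
    return "".join(out)


def read_fasta(
    path: str | Path,
    *,
    ambiguity: Literal["random", "strict"] = "random",
    seed: int = 0,
) -> list[DnaSequence]:
    """Read a FASTA file into a list of :class:`DnaSequence`.

    Lowercase residues are canonicalized to uppercase.  IUPAC ambiguity codes
    are replaced by a uniformly random compatible canonical base drawn from
    ``seed`` (default policy), or rejected when ``ambiguity='strict'``.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: content before first FASTA header")
    rng = np.random.default_rng(seed)
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    return [
        DnaSequence(id=rec.id, bases=_canonicalize(str(rec.seq), rec.id, ambiguity=ambiguity, rng=rng))
        for rec in records
    ]


def write_fasta(path: str | Path, sequences: Sequence[DnaSequence], *, width: int = 70) -> None:
    """Write sequences as 70-column wrapped FASTA records."""
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in sequences]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def generate_dna(spec: SyntheticSpec) -> DnaSequence:
    """Draw a synthetic DNA sequence under ``spec``; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.length == 0:
        return DnaSequence(id=_spec_id(spec), bases="")
    probs = np.asarray(spec.base_probs, dtype=float)
    if spec.model == "uniform":
        idx = rng.choice(4, size=spec.length, p=probs / probs.sum())
    else:
        # start from the stationary distribution of the chain
        evals, evecs = np.linalg.eig(probs.T)
        k = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        idx = np.empty(spec.length, dtype=np.int64)
        idx[0] = rng.choice(4, p=pi)
        rows_cum = probs.cumsum(axis=1)
        u = rng.random(spec.length)
        for t in range(1, spec.length):
            idx[t] = np.searchsorted(rows_cum[idx[t - 1]], u[t])
    bases = "".join(CANONICAL[i] for i in idx)
    return DnaSequence(id=_spec_id(spec), bases=bases)


def _spec_id(spec: SyntheticSpec) -> str:
    return f"synthetic_{spec.model}_n{spec.length}_seed{spec.seed}"


def generate_arfima_series(
    n: int,
    p: int = 0,
    d: float = 0.0,
    q: int = 0,
    ar_coeffs: Sequence[float] = (),
    ma_coeffs: Sequence[float] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
    burn_in: int = 500,
) -> np.ndarray:
    """Simulate an ARFIMA(p, d, q) series with known parameters.

    White noise is passed through the MA polynomial, the AR recursion, and
    finally the inverse fractional-differencing filter (1-B)^{-d}.  A burn-in
    segment absorbs the transient of the AR recursion and is discarded.
    """
    from .arfima import frac_integrate  # local import: avoid cycle at module load

    if abs(d) >= 0.5:
        raise ValueError("fractional order must satisfy |d| < 0.5")
    ar = np.asarray(ar_coeffs, dtype=float)
    ma = np.asarray(ma_coeffs, dtype=float)
    if len(ar) != p or len(ma) != q:
        raise ValueError("coefficient lengths must match the stated orders")
    if p and np.min(np.abs(np.roots(np.r_[-ar[::-1], 1.0]))) <= 1.0:
        raise ValueError("AR polynomial roots must lie outside the unit circle")
    if q and np.min(np.abs(np.roots(np.r_[ma[::-1], 1.0]))) <= 1.0:
        raise ValueError("MA polynomial roots must lie outside the unit circle")

    rng = np.random.default_rng(seed)
    total = n + burn_in
    e = rng.normal(0.0, noise_sd, size=total)
    # MA part
    u = e.copy()
    for j in range(q):
        u[j + 1:] += ma[j] * e[: total - j - 1]
    # AR recursion
    v = np.empty(total)
    for t in range(total):
        acc = u[t]
        for i in range(min(p, t)):
            acc += ar[i] * v[t - i - 1]
        v[t] = acc
    v = v[burn_in:]
    if d == 0.0:
        return v
    return frac_integrate(v, d)


def series_to_csv(path: str | Path, values: np.ndarray, *, value_col: str = "value") -> None:
    """Export a numeric series as two-column CSV (index, value) with header."""
    arr = np.asarray(values, dtype=float)
    pd.DataFrame({"index": np.arange(arr.size), value_col: arr}).to_csv(path, index=False)


def series_from_csv(path: str | Path) -> np.ndarray:
    """Read a series written by :func:`series_to_csv` (second column)."""
    df = pd.read_csv(path)
    return df.iloc[:, 1].to_numpy(dtype=float)
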