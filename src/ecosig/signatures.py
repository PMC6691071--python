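"""Tetranucleotide usage Z-score genome signatures.

A genome's "signature" is the vector of deviations of its observed
tetranucleotide counts from the expectation under a maximal-order Markov
model built from its own tri- and di-nucleotide counts.  Counts are taken
over the sequence and its reverse complement (each strand counted
separately, so no artificial windows span a junction), which makes every
signature exactly symmetric under reverse complementation.

For a tetranucleotide w = n1 n2 n3 n4:

    E(w)   = N(n1 n2 n3) * N(n2 n3 n4) / N(n2 n3)
    var(w) = E(w) * (N(n2 n3) - N(n1 n2 n3)) * (N(n2 n3) - N(n2 n3 n4)) / N(n2 n3)^2
    Z(w)   = (N(w) - E(w)) / sqrt(var(w))

with Z(w) = 0 by convention when E(w) = 0 or var(w) = 0 (such cells carry
no deviation information and 0 is neutral in downstream distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "KmerCounts",
    "TetraZProfile",
    "TETRANUCLEOTIDES",
    "reverse_complement",
    "count_kmers",
    "expected_counts",
    "zscore_profile",
    "signature_matrix",
    "read_fasta",
    "write_signature_tsv",
    "read_signature_tsv",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: All 256 tetranucleotides in fixed lexicographic order (AAAA ... TTTT).
TETRANUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in product(_BASES, repeat=4)
)

_VALID_CHARS = frozenset("ACGTN")

# byte -> base code lookup; A,C,G,T -> 0..3, N -> -1, anything else -> -2
_CODE = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = -1
_CODE[ord("n")] = -1


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _rc_code_permutation(k: int) -> np.ndarray:
    """Permutation p with p[code(w)] = code(reverse_complement(w)) for k-mers."""
    w = np.arange(4**k)
    out = np.zeros_like(w)
    x = w.copy()
    for _ in range(k):
        out = out * 4 + (3 - (x % 4))
        x //= 4
    return out


_RC_PERM = {k: _rc_code_permutation(k) for k in (2, 3, 4)}


def _kmer_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASES.index(ch)
    return idx


@dataclass(frozen=True)
class SequenceRecord:
    """A labelled DNA sequence (phage genome, bacterial chromosome, ...).

    The sequence is uppercased on construction; characters outside
    {A,C,G,T,N} are rejected (RNA 'U' included), and the sequence must be
    at least 4 nt long.
    """

    id: str
    sequence: str
    role: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.role not in ("phage", "bacterium", "other"):
            raise ValueError(f"unknown role {self.role!r}")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: "
                f"{sorted(bad)} (DNA over A,C,G,T,N expected)"
            )
        if len(seq) < 4:
            raise ValueError(f"sequence {self.id!r} shorter than 4 nt")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class KmerCounts:
    """k-mer counts over a sequence plus its reverse complement.

    ``counts[i]`` is the count of the k-mer with lexicographic code ``i``.
    ``n_windows`` is the number of N-free windows counted (both strands).
    """

    k: int
    counts: np.ndarray
    n_windows: int
    sequence_id: str = ""

    def __getitem__(self, kmer: str) -> int:
        return int(self.counts[_kmer_index(kmer.upper())])

    def as_dict(self) -> dict[str, int]:
        kmers = ("".join(p) for p in product(_BASES, repeat=self.k))
        return {w: int(c) for w, c in zip(kmers, self.counts)}


@dataclass(frozen=True)
class TetraZProfile:
    """256-dimensional tetranucleotide Z-score vector for one sequence."""

    sequence_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != (256,):
            raise ValueError("profile must have exactly 256 entries")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("profile contains non-finite values")

    def __getitem__(self, kmer: str) -> float:
        return float(self.z[_kmer_index(kmer.upper())])

    def as_series(self) -> pd.Series:
        return pd.Series(self.z, index=list(TETRANUCLEOTIDES), name=self.sequence_id)


def _sequence_codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == -2):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return codes


def _count_strand(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Counts of k-mer codes over N-free windows of one strand."""
    n_win = codes.size - k + 1
    if n_win <= 0:
        return np.zeros(4**k, dtype=np.int64), 0
    kcodes = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        valid &= c >= 0
        kcodes = kcodes * 4 + np.where(c >= 0, c, 0)
    counts = np.bincount(kcodes[valid], minlength=4**k).astype(np.int64)
    return counts, int(valid.sum())


def count_kmers(record: SequenceRecord | str, k: int) -> KmerCounts:
    """Count k-mers (k in {2,3,4}) over a sequence and its reverse complement.

    Each strand is counted separately over a 1 nt sliding window and the two
    counts summed, so no window spans a strand junction.  Windows containing
    N are skipped on both strands.  For an N-free sequence of length L the
    counts sum to 2*(L-k+1).
    """
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    if isinstance(record, SequenceRecord):
        seq, seq_id = record.sequence, record.id
    else:
        seq, seq_id = record.upper(), ""
    if len(seq) < k:
        raise ValueError("sequence too short")
    codes = _sequence_codes(seq)
    fwd, n_fwd = _count_strand(codes, k)
    # counting the reverse-complement strand is equivalent to adding the
    # forward count of each k-mer's reverse complement
    counts = fwd + fwd[_RC_PERM[k]]
    return KmerCounts(k=k, counts=counts, n_windows=2 * n_fwd, sequence_id=seq_id)


def expected_counts(
    c4: KmerCounts, c3: KmerCounts, c2: KmerCounts
) -> np.ndarray:
    """Expected tetranucleotide counts under the maximal-order Markov model.

    E(n1n2n3n4) = N(n1n2n3) * N(n2n3n4) / N(n2n3), with E = 0 when the
    central dinucleotide never occurs.  Returns a length-256 array in
    lexicographic tetranucleotide order.
    """
    if (c4.k, c3.k, c2.k) != (4, 3, 2):
        raise ValueError("expected counts for k = 4, 3, 2 in that order")
    ids = {c.sequence_id for c in (c4, c3, c2) if c.sequence_id}
    if len(ids) > 1:
        raise ValueError(f"counts come from different sequences: {sorted(ids)}")
    w = np.arange(256)
    n3 = c3.counts.astype(float)
    n2 = c2.counts.astype(float)
    prefix = w >> 2          # n1 n2 n3
    suffix = w & 0x3F        # n2 n3 n4
    mid = prefix & 0xF       # n2 n3
    denom = n2[mid]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, n3[prefix] * n3[suffix] / np.maximum(denom, 1), 0.0)
    return e


def zscore_profile(record: SequenceRecord) -> TetraZProfile:
    """Tetranucleotide Z-score profile of one sequence.

    Raises if every window is masked by N (no countable windows).
    """
    c2 = count_kmers(record, 2)
    c3 = count_kmers(record, 3)
    c4 = count_kmers(record, 4)
    if min(c2.n_windows, c3.n_windows, c4.n_windows) == 0:
        raise ValueError(f"no countable windows in sequence {record.id!r}")
    e = expected_counts(c4, c3, c2)

    w = np.arange(256)
    n3 = c3.counts.astype(float)
    n2 = c2.counts.astype(float)
    prefix = w >> 2
    suffix = w & 0x3F
    mid = prefix & 0xF
    denom = n2[mid]
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            denom > 0,
            e * (denom - n3[prefix]) * (denom - n3[suffix]) / np.maximum(denom, 1) ** 2,
            0.0,
        )
    z = np.zeros(256)
    ok = (var > 0) & (e > 0)
    z[ok] = (c4.counts[ok] - e[ok]) / np.sqrt(var[ok])
    # enforce bitwise reverse-complement symmetry: both cells of a (w, rc(w))
    # pair take the value computed for the lexicographically smaller one
    z = z[np.minimum(w, _RC_PERM[4])]
    return TetraZProfile(sequence_id=record.id, z=z)


def signature_matrix(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Stack Z-score profiles into a (sequences x 256) signature matrix.

    Rows follow input order; columns are the 256 tetranucleotides in
    lexicographic order.  Requires at least 2 records with unique ids.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("signature matrix requires at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    rows = np.vstack([zscore_profile(r).z for r in records])
    df = pd.DataFrame(rows, index=ids, columns=list(TETRANUCLEOTIDES))
    df.index.name = "sequence_id"
    return df


def read_fasta(
    path: str | Path,
    role: str = "other",
    min_length: int = 4,
    roles: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Read a multi-FASTA into SequenceRecords.

    The id is the description line up to the first whitespace.  ``roles``
    optionally maps ids to per-record roles; unknown ids fall back to
    ``role``.  Records shorter than ``min_length`` are dropped.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if len(seq) < min_length:
            continue
        r = roles.get(rec.id, role) if roles else role
        out.append(SequenceRecord(id=rec.id, sequence=seq, role=r))
    return out


def write_signature_tsv(sig: pd.DataFrame, path: str | Path) -> None:
    """Write a signature matrix as TSV with floats at 6 decimal places."""
    sig.to_csv(path, sep="\t", float_format="%.6f", index_label="sequence_id")


def read_signature_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sequence_id")
    if list(df.columns) != list(TETRANUCLEOTIDES):
        raise ValueError("not a tetranucleotide signature matrix")
    return df
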