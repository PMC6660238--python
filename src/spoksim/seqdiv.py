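"""Sliding-window sequence diversity: per-site pairwise differences, variable
sites and GC content.

``windowed_pi`` reimplements the study's custom diversity statistic: for each
bi-allelic site the average pairwise nucleotide difference with the small-
sample correction n/(n−1), ignoring any site containing a gap, averaged in
overlapping windows (default 100 bp windows, 20 bp steps).  GC content uses
4-kb windows with 2-kb steps by default.  Coordinates are 0-based half-open
``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP_STATES = (b"-", b"N")
BASES = (b"A", b"C", b"G", b"T")


@dataclass
class Alignment:
    """≥2 equal-length sequences over {A, C, G, T, -, N}."""

    labels: List[str]
    matrix: np.ndarray  # (n_sequences, length), dtype S1, upper-case

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 2:
            raise ValueError("alignment needs >= 2 equal-length sequences")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per sequence required")

    @classmethod
    def from_sequences(cls, sequences: Sequence[str],
                       labels: Optional[Sequence[str]] = None) -> "Alignment":
        seqs = [s.upper() for s in sequences]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("sequences must have equal lengths")
        labels = list(labels) if labels is not None else [
            f"seq{i}" for i in range(len(seqs))]
        matrix = np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])
        return cls(labels=labels, matrix=matrix)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls.from_sequences([str(r.seq) for r in records],
                                  [r.id for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.matrix):
                fh.write(f">{label}\n{row.tobytes().decode()}\n")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass
class DiversityTrack:
    """Ordered windows of a per-window statistic; 0-based half-open coordinates."""

    records: pd.DataFrame  # columns: start, end, value, n_valid_sites
    window: int
    step: int
    statistic: str = "pi"

    def to_tsv(self, path, label: str = "aln") -> None:
        out = self.records.copy()
        out.insert(0, "label", label)
        with open(path, "w") as fh:
            fh.write(f"# {self.statistic}; window={self.window} "
                     f"step={self.step}; coordinates 0-based half-open "
                     f"[start, end)\n")
            out.to_csv(fh, sep="\t", index=False)

    @property
    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy()


def _window_starts(length: int, window: int, step: int) -> Tuple[List[int], int]:
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if length < window:
        warnings.warn(
            f"window ({window}) exceeds length ({length}); emitting a single "
            f"truncated window", stacklevel=3)
        return [0], length
    return list(range(0, length - window + 1, step)), window


def per_site_pi(aln: Alignment, include_multiallelic: bool = False
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site diversity values and validity mask.

    A site containing any gap (or N) is invalid and excluded from both
    numerator and denominator.  A valid bi-allelic site scores
    2·p̂·(1−p̂)·n/(n−1) (= the mean pairwise difference n1·n2/C(n,2));
    invariant sites score 0.  Sites with more than two states are skipped by
    default, or scored with the multi-allelic heterozygosity
    (1 − Σp̂ᵢ²)·n/(n−1) when ``include_multiallelic`` is set.
    """
    m = aln.matrix
    n = aln.n
    valid = np.ones(aln.length, dtype=bool)
    for g in GAP_STATES:
        valid &= ~(m == g).any(axis=0)
    counts = np.array([(m == b).sum(axis=0) for b in BASES], dtype=float)
    n_states = (counts > 0).sum(axis=0)
    freqs = counts / n
    correction = n / (n - 1)
    values = np.zeros(aln.length)
    bi = valid & (n_states == 2)
    p_major = freqs.max(axis=0)
    values[bi] = 2.0 * p_major[bi] * (1.0 - p_major[bi]) * correction
    multi = valid & (n_states > 2)
    if include_multiallelic:
        het = 1.0 - (freqs ** 2).sum(axis=0)
        values[multi] = het[multi] * correction
    else:
        valid = valid & ~multi
    return values, valid


def windowed_pi(aln: Alignment, window: int = 100, step: int = 20,
                include_multiallelic: bool = False,
                normalize: str = "valid_sites") -> DiversityTrack:
    """Average pairwise nucleotide differences in overlapping windows.

    The window value is the mean of per-site values over the window's valid
    (non-gap) sites by default, or over the full window width with
    ``normalize='window'``.  Windows with no valid site report NaN.
    """
    if normalize not in ("valid_sites", "window"):
        raise ValueError(f"unknown normalization {normalize!r}")
    values, valid = per_site_pi(aln, include_multiallelic)
    starts, width = _window_starts(aln.length, window, step)
    rows = []
    for s in starts:
        e = s + width
        v = values[s:e][valid[s:e]]
        n_valid = int(valid[s:e].sum())
        if normalize == "window":
            val = v.sum() / (e - s)
        else:
            val = v.mean() if n_valid else float("nan")
        rows.append({"start": s, "end": e, "value": val,
                     "n_valid_sites": n_valid})
    return DiversityTrack(records=pd.DataFrame(rows), window=window,
                          step=step, statistic="pi")


def count_variable_sites(aln: Alignment) -> Tuple[int, int]:
    """(variable sites, total sites): sites with ≥2 distinct non-gap states."""
    m = aln.matrix
    counts = np.array([(m == b).sum(axis=0) for b in BASES])
    n_states = (counts > 0).sum(axis=0)
    return int((n_states >= 2).sum()), aln.length


def gc_content_windows(seq: str, window: int = 4000, step: int = 2000
                       ) -> DiversityTrack:
    """GC fraction per window, with N excluded from the denominator."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    gc = (arr == b"G") | (arr == b"C")
    known = np.isin(arr, [b"A", b"C", b"G", b"T"])
    starts, width = _window_starts(len(arr), window, step)
    rows = []
    for s in starts:
        e = s + width
        denom = int(known[s:e].sum())
        val = gc[s:e].sum() / denom if denom else float("nan")
        rows.append({"start": s, "end": e, "value": val,
                     "n_valid_sites": denom})
    return DiversityTrack(records=pd.DataFrame(rows), window=window,
                          step=step, statistic="gc")
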