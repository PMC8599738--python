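"""Domain types and readers/writers for the external formats the pipeline touches.

Every coordinate inside the package is 0-based half-open (BED-native).
Formats that use other conventions are converted at the boundary, never
internally.  All parsers validate and report the offending line number on
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """A file violated its format contract; the message names the line."""


# ---------------------------------------------------------------------------
# Genomic intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval, optionally with a summit.

    ``summit`` is an absolute 0-based coordinate (narrowPeak column-10
    semantics after adding the peak start) and must fall inside
    ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def distance_to_point(self, pos: int) -> int:
        """Edge-to-point distance; 0 if the point lies inside the interval."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


class RegionSet:
    """An ordered collection of :class:`GenomicInterval` over one genome.

    ids, when present, must be unique; every interval must fit inside
    ``chrom_sizes``.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        chrom_sizes: Mapping[str, int],
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        seen: set[str] = set()
        for iv in self.intervals:
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > self.chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.chrom_sizes[iv.chrom]}"
                )
            if iv.id is not None:
                if iv.id in seen:
                    raise ValueError(f"duplicate interval id {iv.id!r}")
                seen.add(iv.id)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def ids(self) -> list[str | None]:
        return [iv.id for iv in self.intervals]

    def by_id(self) -> dict[str, GenomicInterval]:
        return {iv.id: iv for iv in self.intervals if iv.id is not None}

    def subset(self, keep_ids: Iterable[str]) -> "RegionSet":
        keep = set(keep_ids)
        return RegionSet(
            [iv for iv in self.intervals if iv.id in keep], self.chrom_sizes
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": [iv.id for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "summit": [iv.summit for iv in self.intervals],
            }
        )


class IntervalIndex:
    """Merged per-chromosome interval index for fast overlap queries.

    Built once from a feature set; answers "does this interval overlap any
    feature within ``slop`` bp" with two binary searches.
    """

    def __init__(self, features: Iterable[GenomicInterval]) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in features:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, spans in per_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def overlaps_any(self, iv: GenomicInterval, slop: int = 0) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return False
        ends = self._ends[iv.chrom]
        # overlap (with slop) iff some merged feature has
        # start < iv.end + slop and end > iv.start - slop
        k = int(np.searchsorted(starts, iv.end + slop))
        if k == 0:
            return False
        return bool(ends[:k].max(initial=0) > iv.start - slop)

    def count_overlapping_starts(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, slop: int = 0
    ) -> np.ndarray:
        """Vectorised: boolean array, one per query interval on ``chrom``."""
        fs = self._starts.get(chrom)
        if fs is None:
            return np.zeros(len(starts), dtype=bool)
        fe = self._ends[chrom]
        # merged intervals are disjoint and sorted, so cumulative max of ends
        # equals ends itself; query i overlaps iff the last feature starting
        # before ends[i]+slop finishes after starts[i]-slop.
        k = np.searchsorted(fs, ends + slop)
        out = np.zeros(len(starts), dtype=bool)
        nz = k > 0
        out[nz] = fe[k[nz] - 1] > starts[nz] - slop
        return out


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A/C/G/T with a background model.

    ``probs`` has shape ``(width, 4)`` with rows summing to 1; every entry is
    strictly positive after the pseudocount so log-odds are finite.  Log-odds
    scores are in bits: ``sum_j log2(p_j(base) / background(base))``.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if np.any(probs <= 0):
            raise ValueError("all PWM probabilities must be > 0 (pseudocount)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 positive probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/background), shape (width, 4)."""
        return np.log2(self.probs / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        # reverse position order and swap A<->T, C<->G; background likewise
        rc_probs = self.probs[::-1, ::-1].copy()
        rc_bg = self.background[::-1].copy()
        return PWM(self.motif_id + "_rc", rc_probs, rc_bg)


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def gc_background(gc: float = 0.409) -> np.ndarray:
    """Background from GC fraction (default hg19-like 40.9% GC)."""
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def read_jaspar_pfm(
    path,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PWM:
    """Read a JASPAR text PFM into a :class:`PWM`.

    Column probabilities are ``(count + pseudocount * b_base) /
    (colsum + pseudocount)``, i.e. the pseudocount is distributed according
    to the background (FIMO-style).
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    with open(path) as fh:
        text = fh.read()
    motif_id = "motif"
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            motif_id = line[1:].split()[0] if line[1:].split() else "motif"
            continue
        token = line.split()[0].rstrip(":").upper()
        if token in BASES:
            base, payload = token, line.split(maxsplit=1)[1]
        else:
            # bare 4-row matrix: assign rows in A,C,G,T order
            base = BASES[len(order)] if len(order) < 4 else "?"
            payload = line
        payload = payload.replace("[", " ").replace("]", " ")
        try:
            values = [float(v) for v in payload.split()]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable counts") from exc
        if any(v < 0 for v in values):
            raise FormatError(f"{path}:{lineno}: negative count")
        if base in rows:
            raise FormatError(f"{path}:{lineno}: duplicate row for base {base}")
        rows[base] = values
        order.append(base)
    if sorted(rows) != list(BASES):
        raise FormatError(f"{path}: expected exactly one row per base A/C/G/T")
    lengths = {len(rows[b]) for b in BASES}
    if len(lengths) != 1:
        raise FormatError(f"{path}: unequal row lengths {sorted(lengths)}")
    counts = np.array([rows[b] for b in BASES], dtype=float).T  # (width, 4)
    colsum = counts.sum(axis=1, keepdims=True)
    if np.any(colsum <= 0) and pseudocount <= 0:
        raise FormatError(f"{path}: empty column with zero pseudocount")
    probs = (counts + pseudocount * bg[None, :]) / (colsum + pseudocount)
    return PWM(motif_id, probs, bg)


def write_jaspar_pfm(path, motif_id: str, counts: np.ndarray) -> None:
    """Write integer/real counts (width, 4) as a JASPAR text PFM."""
    counts = np.asarray(counts, dtype=float)
    with open(path, "w") as fh:
        fh.write(f">{motif_id}\n")
        for i, base in enumerate(BASES):
            row = " ".join(f"{v:g}" for v in counts[:, i])
            fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class SignalTable:
    """Raw read counts per region per sample with the sample design.

    ``counts``: DataFrame (region ids x sample ids), non-negative integers.
    ``design``: DataFrame indexed by sample with columns ``stage``,
    ``condition``, ``replicate``.  ``size_factors`` is filled by
    :func:`enhancerkit.signal_stats.size_factors`.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        for col in ("stage", "condition", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design lacks required column {col!r}")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def region_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_where(self, **levels: str) -> list[str]:
        """Sample ids whose design matches every keyword (e.g. stage='PP2')."""
        mask = pd.Series(True, index=self.design.index)
        for key, value in levels.items():
            mask &= self.design[key] == value
        return [s for s in self.counts.columns if mask.loc[s]]

    def write_tsv(self, counts_path, design_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="region_id")
        self.design.to_csv(design_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, counts_path, design_path) -> "SignalTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="region_id")
        design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
        if not counts.dtypes.map(pd.api.types.is_integer_dtype).all():
            raise FormatError(f"{counts_path}: non-integer counts")
        return cls(counts=counts, design=design)


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

class ContactMatrix:
    """Symmetric binned intra-chromosomal raw contact counts.

    Stored as the upper triangle (``i <= j``); the mirror image is implied.
    """

    def __init__(self, chrom: str, resolution: int, n_bins: int) -> None:
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        if n_bins <= 0:
            raise ValueError("n_bins must be positive")
        self.chrom = chrom
        self.resolution = resolution
        self.n_bins = n_bins
        self._data: dict[tuple[int, int], float] = {}

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i <= j else (j, i)

    def set(self, i: int, j: int, count: float) -> None:
        if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
            raise ValueError(f"bin ({i},{j}) outside [0,{self.n_bins})")
        if count < 0:
            raise ValueError("counts must be non-negative")
        key = self._key(i, j)
        existing = self._data.get(key)
        if existing is not None and existing != count:
            raise FormatError(
                f"conflicting counts for symmetric pixel {key}: "
                f"{existing} vs {count}"
            )
        self._data[key] = count

    def get(self, i: int, j: int) -> float:
        return self._data.get(self._key(i, j), 0.0)

    def items(self) -> Iterator[tuple[int, int, float]]:
        for (i, j), c in sorted(self._data.items()):
            yield i, j, c

    def nnz(self) -> int:
        return len(self._data)

    def to_dense(self) -> np.ndarray:
        mat = np.zeros((self.n_bins, self.n_bins))
        for (i, j), c in self._data.items():
            mat[i, j] = c
            mat[j, i] = c
        return mat

    @classmethod
    def from_dense(
        cls, chrom: str, resolution: int, dense: np.ndarray
    ) -> "ContactMatrix":
        dense = np.asarray(dense)
        if dense.ndim != 2 or dense.shape[0] != dense.shape[1]:
            raise ValueError("dense matrix must be square")
        if not np.allclose(dense, dense.T):
            raise ValueError("dense matrix must be symmetric")
        cm = cls(chrom, resolution, dense.shape[0])
        ii, jj = np.nonzero(np.triu(dense))
        for i, j in zip(ii.tolist(), jj.tolist()):
            cm._data[(i, j)] = float(dense[i, j])
        return cm


def read_contacts(
    path, resolution: int, chrom_sizes: Mapping[str, int]
) -> dict[str, ContactMatrix]:
    """Read triplet text (chrom, bin_i, bin_j, count) into per-chromosome
    matrices.  Duplicate symmetric entries must agree; conflicts are errors.
    """
    matrices: dict[str, ContactMatrix] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            try:
                i, j = int(parts[1]), int(parts[2])
                count = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable triplet") from exc
            if chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            n_bins = -(-chrom_sizes[chrom] // resolution)
            cm = matrices.setdefault(chrom, ContactMatrix(chrom, resolution, n_bins))
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise FormatError(f"{path}:{lineno}: bin index out of range")
            try:
                cm.set(i, j, count)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return matrices


def write_contacts(path, matrices: Mapping[str, ContactMatrix]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(matrices):
            for i, j, c in matrices[chrom].items():
                fh.write(f"{chrom}\t{i}\t{j}\t{c:g}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak / FASTA
# ---------------------------------------------------------------------------

def _parse_bed_line(
    parts: Sequence[str], path, lineno: int
) -> tuple[str, int, int, str | None, str]:
    if len(parts) < 3:
        raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0:
        raise FormatError(f"{path}:{lineno}: negative start")
    if start >= end:
        raise FormatError(f"{path}:{lineno}: start >= end")
    name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
    strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
    return chrom, start, end, name, strand


def read_bed(path, chrom_sizes: Mapping[str, int]) -> RegionSet:
    """Read a 3+ column BED file; the optional 4th column becomes the id."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, strand = _parse_bed_line(
                line.split("\t"), path, lineno
            )
            if chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise FormatError(
                    f"{path}:{lineno}: interval beyond chromosome end"
                )
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    return RegionSet(intervals, chrom_sizes)


def read_narrowpeak(path, chrom_sizes: Mapping[str, int]) -> RegionSet:
    """Read an ENCODE narrowPeak file; column 10 (summit offset) becomes an
    absolute summit coordinate, or stays absent when it is -1."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            chrom, start, end, name, strand = _parse_bed_line(parts, path, lineno)
            if chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise FormatError(f"{path}:{lineno}: interval beyond chromosome end")
            try:
                offset = int(parts[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer summit") from exc
            if offset >= end - start:
                raise FormatError(
                    f"{path}:{lineno}: summit offset {offset} >= peak length"
                )
            summit = start + offset if offset >= 0 else None
            intervals.append(GenomicInterval(chrom, start, end, name, strand, summit))
    return RegionSet(intervals, chrom_sizes)


def write_bed(path, regions: RegionSet) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            name = iv.id if iv.id is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_narrowpeak(path, regions: RegionSet) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            name = iv.id if iv.id is not None else "."
            offset = iv.summit - iv.start if iv.summit is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
                f"\t0\t-1\t-1\t{offset}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
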