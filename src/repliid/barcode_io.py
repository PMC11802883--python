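"""Reading screen inputs and turning raw reads into per-sample barcode counts.

A pooled screen sample is a FASTQ file of barcode amplicons.  Each read is
expected to carry a fixed anchor sequence immediately 5' of a fixed-length
strain barcode; the :class:`ReadStructure` describes that layout.  Counting a
sample means extracting the barcode from every read, matching it against the
:class:`BarcodeMap` (optionally with single-mismatch correction), and
tallying per-barcode read counts together with QC totals.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_VALID_BASES = frozenset("ACGT")

#: reasons a read can fail barcode assignment
UNASSIGNED_REASONS = ("no_anchor", "short_read", "unknown_barcode", "ambiguous_correction")

_AMBIGUOUS = object()  # sentinel in the 1-mismatch neighbor index


class BarcodeMapError(ValueError):
    """Raised for an invalid barcode map (duplicates, bad alphabet, ragged lengths)."""


class BarcodeMap:
    """Lookup table from barcode sequence to strain identity.

    Parameters
    ----------
    entries
        DataFrame with columns ``barcode``, ``strain_id``, ``gene``,
        ``strain_class`` (values ``mutant`` or ``wildtype``).  Row order is
        preserved.

    All barcodes must share one length, use only A/C/G/T, and be unique;
    strain ids must be unique.  A gene may map to several barcodes only for
    wild-type strains (the pooled wild types form one control population).
    """

    def __init__(self, entries: pd.DataFrame):
        required = ["barcode", "strain_id", "gene", "strain_class"]
        missing = [c for c in required if c not in entries.columns]
        if missing:
            raise BarcodeMapError(f"barcode map missing columns: {missing}")
        df = entries.loc[:, required].reset_index(drop=True).astype(str)
        if len(df) == 0:
            raise BarcodeMapError("barcode map is empty")

        length = len(df.at[0, "barcode"])
        seen: dict[str, int] = {}
        for i, bc in enumerate(df["barcode"]):
            if len(bc) != length:
                raise BarcodeMapError(
                    f"barcode length mismatch at row {i}: {bc!r} has length "
                    f"{len(bc)}, expected {length}"
                )
            if not set(bc) <= _VALID_BASES:
                bad = "".join(sorted(set(bc) - _VALID_BASES))
                raise BarcodeMapError(f"invalid alphabet in barcode {bc!r}: {bad!r}")
            if bc in seen:
                raise BarcodeMapError(f"duplicate barcode {bc!r} (rows {seen[bc]} and {i})")
            seen[bc] = i
        dup_strains = df["strain_id"][df["strain_id"].duplicated()]
        if len(dup_strains):
            raise BarcodeMapError(f"duplicate strain_id {dup_strains.iloc[0]!r}")
        bad_class = set(df["strain_class"]) - {"mutant", "wildtype"}
        if bad_class:
            raise BarcodeMapError(f"invalid strain_class values: {sorted(bad_class)}")
        mut = df[df["strain_class"] == "mutant"]
        dup_genes = mut["gene"][mut["gene"].duplicated()]
        if len(dup_genes):
            raise BarcodeMapError(
                f"gene {dup_genes.iloc[0]!r} maps to multiple mutant barcodes"
            )

        self.entries = df
        self.barcode_length = length
        self._index = seen
        self._neighbors: dict[str, object] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    @property
    def barcodes(self) -> list[str]:
        return list(self.entries["barcode"])

    def strain_of(self, barcode: str) -> str:
        return self.entries.at[self._index[barcode], "strain_id"]

    def _neighbor_index(self) -> dict[str, object]:
        # map every sequence at Hamming distance 1 from a barcode to that
        # barcode; collisions (two barcodes sharing a neighbor) are marked
        # ambiguous.  Built lazily: only the hamming1 policy needs it.
        if self._neighbors is None:
            idx: dict[str, object] = {}
            for bc in self._index:
                for pos in range(self.barcode_length):
                    for base in "ACGT":
                        if base == bc[pos]:
                            continue
                        nb = bc[:pos] + base + bc[pos + 1 :]
                        if nb in idx and idx[nb] != bc:
                            idx[nb] = _AMBIGUOUS
                        else:
                            idx[nb] = bc
            self._neighbors = idx
        return self._neighbors

    def correct_hamming1(self, candidate: str):
        """Return (barcode, reason): the unique map barcode at Hamming
        distance 1 from ``candidate``, or ``(None, reason)``."""
        if candidate in self._index:
            return candidate, None
        hit = self._neighbor_index().get(candidate)
        if hit is None:
            return None, "unknown_barcode"
        if hit is _AMBIGUOUS:
            return None, "ambiguous_correction"
        return hit, None

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def load_barcode_map(path: str | Path) -> BarcodeMap:
    """Read a barcode map TSV (columns barcode, strain_id, gene, strain_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return BarcodeMap(df)


@dataclass(frozen=True)
class ReadStructure:
    """Layout of a barcode amplicon read.

    ``anchor`` is the constant sequence expected immediately 5' of the
    barcode; it may begin anywhere in ``search_window`` (0-based half-open,
    ``None`` meaning the whole read) and may carry up to
    ``anchor_max_mismatch`` substitutions.  The ``barcode_length`` bases
    following the anchor are the candidate barcode.  An empty anchor means
    the barcode starts directly at the window start.
    """

    anchor: str = ""
    anchor_max_mismatch: int = 0
    barcode_length: int = 20
    search_window: tuple[int, int] | None = None

    def __post_init__(self):
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        if self.anchor_max_mismatch < 0:
            raise ValueError("anchor_max_mismatch must be >= 0")
        if not set(self.anchor) <= _VALID_BASES:
            raise ValueError("anchor must be A/C/G/T only")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced sample: role (IP or input), timepoint
    in minutes after S-phase release, and replicate screen index."""

    sample_id: str
    role: str
    timepoint: int
    replicate: int

    def __post_init__(self):
        if self.role not in ("IP", "input"):
            raise ValueError(f"role must be 'IP' or 'input', got {self.role!r}")


@dataclass
class SampleCounts:
    """Per-sample barcode read counts with QC tallies.

    Invariant: ``assigned_reads + unassigned_reads == total_reads`` and
    ``assigned_reads == sum(counts.values())``.  Every map barcode is
    present in ``counts`` (zero if unseen).
    """

    sample: SampleMeta
    counts: dict[str, int]
    total_reads: int
    assigned_reads: int
    unassigned_reads: int
    unassigned_reasons: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        if self.assigned_reads + self.unassigned_reads != self.total_reads:
            raise ValueError("assigned + unassigned != total")
        if sum(self.counts.values()) != self.assigned_reads:
            raise ValueError("sum of counts != assigned_reads")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative count")

    @property
    def assignment_rate(self) -> float:
        return self.assigned_reads / self.total_reads if self.total_reads else float("nan")


def _mismatches_within(a: str, b: str, limit: int) -> bool:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return False
    return True


def extract_barcode(
    read: str,
    structure: ReadStructure,
    barcode_map: BarcodeMap,
    policy: str = "exact",
):
    """Locate the barcode in one read.

    Returns ``(barcode, None)`` on success or ``(None, reason)`` with reason
    in ``{no_anchor, short_read, unknown_barcode, ambiguous_correction}``.
    The leftmost acceptable anchor position wins; under the ``hamming1``
    policy an unknown candidate is corrected to the unique map barcode at
    Hamming distance 1 if one exists.
    """
    if policy not in ("exact", "hamming1"):
        raise ValueError(f"unknown policy {policy!r}")
    anchor = structure.anchor
    L = barcode_map.barcode_length
    w0, w1 = structure.search_window or (0, len(read))
    w0 = max(0, w0)
    w1 = min(w1, len(read))

    if anchor:
        # leftmost anchor start in [w0, w1) with <= anchor_max_mismatch subs
        pos = -1
        if structure.anchor_max_mismatch == 0:
            p = read.find(anchor, w0, w1 + len(anchor) - 1)
            if p != -1 and p < w1:
                pos = p
        else:
            last = min(w1, len(read) - len(anchor) + 1)
            for p in range(w0, last):
                if _mismatches_within(
                    read[p : p + len(anchor)], anchor, structure.anchor_max_mismatch
                ):
                    pos = p
                    break
        if pos < 0:
            return None, "no_anchor"
        start = pos + len(anchor)
    else:
        start = w0

    candidate = read[start : start + L]
    if len(candidate) < L:
        return None, "short_read"
    if candidate in barcode_map:
        return candidate, None
    if policy == "hamming1":
        return barcode_map.correct_hamming1(candidate)
    return None, "unknown_barcode"


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(handle: IO[str]) -> Iterable[str]:
    """Yield read sequences; re-raise parse failures with the record index."""
    it = FastqGeneralIterator(handle)
    i = 0
    while True:
        try:
            _, seq, _ = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ at record {i + 1}: {exc}") from exc
        i += 1
        yield seq


def count_barcodes(
    reads: str | Path | IO[str] | Iterable[str],
    barcode_map: BarcodeMap,
    structure: ReadStructure | None = None,
    policy: str = "exact",
    sample: SampleMeta | None = None,
) -> SampleCounts:
    """Count barcodes over a FASTQ file (optionally gzipped), an open text
    handle, or an iterable of read sequences.

    Every map barcode appears in the result, zero-count barcodes included.
    Unassignable reads are tallied by reason, never an error.
    """
    structure = structure or ReadStructure(barcode_length=barcode_map.barcode_length)
    if sample is None:
        sample = SampleMeta("sample", "input", 40, 1)

    if isinstance(reads, (str, Path)):
        with _open_maybe_gzip(reads) as fh:
            seqs: Iterable[str] = list(_iter_fastq(fh))
    elif hasattr(reads, "read"):
        seqs = list(_iter_fastq(reads))  # type: ignore[arg-type]
    else:
        seqs = reads

    counts = dict.fromkeys(barcode_map.barcodes, 0)
    reasons: Counter = Counter()
    total = assigned = 0
    for seq in seqs:
        total += 1
        bc, reason = extract_barcode(seq, structure, barcode_map, policy)
        if bc is None:
            reasons[reason] += 1
        else:
            counts[bc] += 1
            assigned += 1
    result = SampleCounts(
        sample=sample,
        counts=counts,
        total_reads=total,
        assigned_reads=assigned,
        unassigned_reads=total - assigned,
        unassigned_reasons=reasons,
    )
    result.validate()
    return result


# ---------------------------------------------------------------------------
# tabular I/O

def counts_to_frame(counts: SampleCounts, barcode_map: BarcodeMap) -> pd.DataFrame:
    df = barcode_map.entries.copy()
    df["count"] = [counts.counts[bc] for bc in df["barcode"]]
    return df


def write_counts_tsv(counts: SampleCounts, barcode_map: BarcodeMap, path: str | Path) -> None:
    counts_to_frame(counts, barcode_map).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, sample: SampleMeta) -> SampleCounts:
    """Load a counts TSV written by :func:`write_counts_tsv`.

    Total reads equal assigned reads here: the unassigned tally lives in the
    QC table, not the per-barcode one.
    """
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "count": int})
    counts = dict(zip(df["barcode"], df["count"].astype(int)))
    assigned = int(sum(counts.values()))
    sc = SampleCounts(sample, counts, assigned, assigned, 0)
    sc.validate()
    return sc


def write_qc_tsv(all_counts: Iterable[SampleCounts], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample.sample_id,
            "total": c.total_reads,
            "assigned": c.assigned_reads,
            "unassigned": c.unassigned_reads,
            "assignment_rate": c.assignment_rate,
        }
        for c in all_counts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, fastq_path, role, timepoint, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fastq_path", "role", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    df["timepoint"] = df["timepoint"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    bad = set(df["role"]) - {"IP", "input"}
    if bad:
        raise ValueError(f"sample sheet role must be IP or input, got {sorted(bad)}")
    keys = list(zip(df["role"], df["timepoint"], df["replicate"]))
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (role, timepoint, replicate) in sample sheet")
    return df
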