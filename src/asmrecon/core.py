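"""Domain types and file I/O shared by every pipeline stage.

Coordinate conventions: all coordinates are 0-based half-open internally
and in every BED/TSV report. AGP output follows the AGP v2.0 standard and
is therefore 1-based inclusive.

A *gap* is a maximal run of at least ``min_gap_len`` (default 10)
consecutive ``N`` bases in a scaffold; *contigs* are the complementary
maximal stretches containing no gap-qualifying N-run. Shorter N-runs are
contig-internal bases, not gaps.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("asmrecon")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: bases kept verbatim on read; any other letter is normalized to N
_CANONICAL = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ToolConfig:
    """All numeric thresholds used across the toolkit.

    Lengths are in bp, identities are fractions in (0, 1].
    """

    min_gap_len: int = 10          # N-run length that qualifies as a gap
    flank_len: int = 1000          # gap flank extracted for cross-mapping
    min_flank_len: int = 200       # shorter flanks are unusable
    max_indel_edit: int = 5        # polishing corrects indels strictly < 6 bp
    wgac_min_len: int = 1000       # WGAC: duplicated blocks >= 1 kbp
    wgac_min_ident: float = 0.90   # WGAC: >= 90% identity
    wssd_min_len: int = 10_000     # WSSD: calls >= 10 kbp
    wssd_read_ident: float = 0.94  # WSSD: reads placed at > 94% identity
    insert_mean: float = 40_000.0  # fosmid-scale insert
    insert_sd: float = 4_000.0
    discord_sds: float = 3.0       # insert-size concordance band, in SDs
    min_discord_cluster: int = 3   # discordant pairs needed to call a break
    perm_reps: int = 10_000        # permutation-test replicates
    rng_seed: int = 0
    # alignment / classification knobs
    kmer_size: int = 15
    uniqueness_margin: float = 0.20  # best score must exceed 2nd by this frac
    max_fill_span: int = 100_000
    min_hit_cov: float = 0.5       # flank hit must cover this fraction of flank
    min_hit_ident: float = 0.90
    # polishing
    min_depth: int = 5
    min_allele_frac: float = 0.8
    guard_bp: int = 10             # no edits within this many bp of a gap
    # WSSD windowing
    wssd_window: int = 5000
    wssd_step: int = 1000
    wssd_depth_sds: float = 3.0
    wssd_merge_slop: int = 2       # unflagged windows tolerated inside a run

    def __post_init__(self) -> None:
        for name in ("min_gap_len", "flank_len", "min_flank_len", "wgac_min_len",
                     "wssd_min_len", "kmer_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("wgac_min_ident", "wssd_read_ident", "min_allele_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.perm_reps < 1:
            raise ValueError("perm_reps must be >= 1")
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be positive")


# ---------------------------------------------------------------------------
# assembly containers


@dataclass(frozen=True)
class GapRecord:
    """A maximal N-run of qualifying length within a scaffold."""

    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Scaffold:
    name: str
    sequence: str
    softmask: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def gaps(self, min_gap_len: int = 10) -> list[GapRecord]:
        return scan_gaps(self.name, self.sequence, min_gap_len)

    def contigs(self, min_gap_len: int = 10) -> list[tuple[int, int]]:
        """Half-open intervals of the maximal gap-free stretches."""
        out = []
        pos = 0
        for g in self.gaps(min_gap_len):
            if g.start > pos:
                out.append((pos, g.start))
            pos = g.end
        if pos < len(self.sequence):
            out.append((pos, len(self.sequence)))
        return out


@dataclass
class Assembly:
    name: str
    scaffolds: list[Scaffold]
    version: str | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scaffold names in assembly")
        self._by_name = {s.name: s for s in self.scaffolds}

    def __getitem__(self, name: str) -> Scaffold:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self.scaffolds)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    def copy(self, name: str | None = None) -> "Assembly":
        return Assembly(name or self.name,
                        [Scaffold(s.name, s.sequence, list(s.softmask))
                         for s in self.scaffolds])


def scan_gaps(scaffold: str, sequence: str, min_gap_len: int) -> list[GapRecord]:
    """All maximal N-runs of length >= min_gap_len, via a vectorized scan."""
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    if not sequence:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    if not is_n.any():
        return []
    padded = np.concatenate(([False], is_n, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    keep = (ends - starts) >= min_gap_len
    return [GapRecord(scaffold, int(s), int(e))
            for s, e in zip(starts[keep], ends[keep])]


def gap_census(asm: Assembly, min_gap_len: int = 10) -> list[GapRecord]:
    """All qualifying gaps in the assembly, sorted by (scaffold order, start)."""
    out: list[GapRecord] = []
    for scaf in asm:
        out.extend(scan_gaps(scaf.name, scaf.sequence, min_gap_len))
    return out


# ---------------------------------------------------------------------------
# alignment record


@dataclass
class AlignmentRecord:
    """A generic pairwise local alignment in 0-based half-open coordinates.

    For strand '-', query_start/query_end are still given on the original
    (forward) query, PAF-style.
    """

    query_name: str
    query_start: int
    query_end: int
    query_len: int
    target_name: str
    target_start: int
    target_end: int
    target_len: int
    strand: str
    matches: int
    aligned_columns: int
    score: float = 0.0
    cigar: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"bad query interval for {self.query_name}")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(f"bad target interval for {self.query_name}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.aligned_columns <= 0 or not 0 <= self.matches <= self.aligned_columns:
            raise ValueError("matches/aligned_columns inconsistent")

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns


def cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(reference_consumed, query_consumed, aligned_columns) for a CIGAR.

    Accepts both plain M and extended =/X match ops.
    """
    ref = qry = cols = 0
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n)
        if op in "M=X":
            ref += n; qry += n; cols += n
        elif op == "I":
            qry += n; cols += n
        elif op in "DN":
            ref += n; cols += n
        elif op in "SH":
            qry += n if op == "S" else 0
    return ref, qry, cols


def cigar_matches(cigar: str, nm: int) -> tuple[int, int]:
    """(matches, aligned_columns) given a CIGAR and its NM edit distance."""
    _, _, cols = cigar_stats(cigar)
    n_i = sum(int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar) if op == "I")
    n_d = sum(int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar) if op in "DN")
    m_cols = cols - n_i - n_d
    mismatches = nm - n_i - n_d
    if mismatches < 0 or mismatches > m_cols:
        raise ValueError(f"NM={nm} inconsistent with CIGAR {cigar}")
    return m_cols - mismatches, cols


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, normalize_ambiguous: bool = True) -> Assembly:
    """Read a (possibly gzipped) multi-FASTA into an Assembly.

    Sequences are uppercased; the scaffold name is the header token before
    the first whitespace. Lowercase (soft-masked) stretches are retained as
    per-scaffold intervals. Non-ACGTN IUPAC codes are converted to N (with
    a logged count) unless ``normalize_ambiguous`` is False.
    """
    path = Path(path)
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    n_ambig = 0
    opener = _open_text(path)
    with opener as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.id
            if name in seen:
                raise ValueError(f"duplicate scaffold name {name!r} in {path}")
            seen.add(name)
            raw = str(rec.seq)
            if not raw:
                raise ValueError(f"empty record {name!r} in {path}")
            softmask = _lowercase_runs(raw)
            seq = raw.upper()
            if normalize_ambiguous:
                seq, n = _normalize_ambiguous(seq)
                n_ambig += n
            scaffolds.append(Scaffold(name, seq, softmask))
    if not scaffolds:
        raise ValueError(f"no FASTA records in {path}")
    if n_ambig:
        logger.info("read_fasta(%s): %d ambiguous bases converted to N",
                    path.name, n_ambig)
    return Assembly(path.stem, scaffolds)


def _open_text(path: Path):
    if path.suffix == ".gz":
        import gzip
        return gzip.open(path, "rt")
    return open(path)


def _lowercase_runs(seq: str) -> list[tuple[int, int]]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    low = (arr >= ord("a")) & (arr <= ord("z"))
    if not low.any():
        return []
    padded = np.concatenate(([False], low, [False]))
    diff = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(diff == 1).tolist(),
                    np.flatnonzero(diff == -1).tolist()))


def _normalize_ambiguous(seq: str) -> tuple[str, int]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    ok = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    n = int((~ok).sum())
    if n:
        arr[~ok] = ord("N")
        return arr.tobytes().decode("ascii"), n
    return seq, 0


def write_fasta(asm: Assembly, path: str | Path, line_width: int = 60) -> Path:
    """Write the assembly as FASTA; round-trips exactly through read_fasta."""
    path = Path(path)
    with open(path, "w") as fh:
        for scaf in asm:
            fh.write(f">{scaf.name}\n")
            seq = scaf.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
    return path


# ---------------------------------------------------------------------------
# AGP v2.0


@dataclass(frozen=True)
class AgpRow:
    object: str
    object_beg: int   # 1-based inclusive, per the AGP standard
    object_end: int
    part_number: int
    component_type: str           # W (sequence) or N/U (gap)
    component_id: str | None      # W rows
    component_beg: int | None
    component_end: int | None
    orientation: str | None
    gap_length: int | None        # N/U rows
    gap_type: str | None


def assembly_to_agp(asm: Assembly, min_gap_len: int = 10) -> list[AgpRow]:
    """Describe each scaffold as alternating contig (W) and gap (N) rows."""
    rows: list[AgpRow] = []
    for scaf in asm:
        gaps = scaf.gaps(min_gap_len)
        parts: list[tuple[int, int, bool]] = []  # (start, end, is_gap)
        pos = 0
        for g in gaps:
            if g.start > pos:
                parts.append((pos, g.start, False))
            parts.append((g.start, g.end, True))
            pos = g.end
        if pos < len(scaf):
            parts.append((pos, len(scaf), False))
        ctg = 0
        for i, (s, e, is_gap) in enumerate(parts, start=1):
            if is_gap:
                rows.append(AgpRow(scaf.name, s + 1, e, i, "N", None, None,
                                   None, None, e - s, "scaffold"))
            else:
                ctg += 1
                rows.append(AgpRow(scaf.name, s + 1, e, i, "W",
                                   f"{scaf.name}_ctg{ctg}", 1, e - s, "+",
                                   None, None))
    return rows


def write_agp(asm: Assembly, path: str | Path, min_gap_len: int = 10) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for r in assembly_to_agp(asm, min_gap_len):
            if r.component_type == "W":
                cols = [r.object, r.object_beg, r.object_end, r.part_number,
                        "W", r.component_id, r.component_beg, r.component_end,
                        r.orientation]
            else:
                cols = [r.object, r.object_beg, r.object_end, r.part_number,
                        "N", r.gap_length, r.gap_type, "yes", "align_genus"]
            fh.write("\t".join(str(c) for c in cols) + "\n")
    return path


def read_agp(path: str | Path) -> list[AgpRow]:
    """Parse and validate an AGP v2.0 file.

    Hard errors (with the offending line number) on overlapping or
    non-contiguous object coordinates and on span/coordinate mismatches —
    the symptoms of 1-based/0-based mixing.
    """
    path = Path(path)
    rows: list[AgpRow] = []
    expected_beg: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: AGP row has {len(f)} columns")
            obj, beg, end, part, ctype = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
            if beg < 1 or end < beg:
                raise ValueError(f"{path}:{lineno}: bad object coordinates "
                                 f"{beg}-{end} (AGP is 1-based inclusive)")
            want = expected_beg.get(obj, 1)
            if beg < want:
                raise ValueError(f"{path}:{lineno}: object {obj} coordinates "
                                 f"overlap previous row (got {beg}, expected {want})")
            if beg != want:
                raise ValueError(f"{path}:{lineno}: object {obj} rows are not "
                                 f"contiguous (got {beg}, expected {want})")
            expected_beg[obj] = end + 1
            if ctype in ("N", "U"):
                gap_len = int(f[5])
                if gap_len != end - beg + 1:
                    raise ValueError(f"{path}:{lineno}: gap length {gap_len} "
                                     f"does not match span {end - beg + 1}")
                rows.append(AgpRow(obj, beg, end, part, ctype, None, None,
                                   None, None, gap_len, f[6]))
            else:
                comp_beg, comp_end = int(f[6]), int(f[7])
                if comp_end - comp_beg != end - beg:
                    raise ValueError(f"{path}:{lineno}: component span does "
                                     f"not match object span")
                rows.append(AgpRow(obj, beg, end, part, ctype, f[5],
                                   comp_beg, comp_end,
                                   f[8] if len(f) > 8 else "+", None, None))
    return rows


def agp_gaps(rows: Sequence[AgpRow]) -> list[GapRecord]:
    """Gap rows as 0-based half-open GapRecords (for census cross-checks)."""
    return [GapRecord(r.object, r.object_beg - 1, r.object_end)
            for r in rows if r.component_type in ("N", "U")]


# ---------------------------------------------------------------------------
# BED


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path) -> list[BedInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            out.append(BedInterval(f[0], start, end, f[3] if len(f) > 3 else "."))
    return out


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
    return path


# ---------------------------------------------------------------------------
# interval algebra (sorted sweeps)


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted((s, e) for s, e in ivs if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union_bp(ivs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


def intersect_bp(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> int:
    """Total overlap between two interval sets on one sequence."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def subtract_intervals(a: Iterable[tuple[int, int]],
                       b: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """a minus b, both half-open interval sets on one sequence."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        pos = s
        while j < len(b) and b[j][1] <= pos:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > pos:
                out.append((pos, b[k][0]))
            pos = max(pos, b[k][1])
            k += 1
        if pos < e:
            out.append((pos, e))
    return out


# ---------------------------------------------------------------------------
# PAF / SAM alignment import


def read_alignments(path: str | Path, dialect: str = "PAF",
                    on_error: str = "raise") -> list[AlignmentRecord]:
    """Read pairwise alignments from PAF (minimap2 dialect) or SAM.

    Identity is computed as matches/aligned_columns; for SAM it is derived
    from the CIGAR plus the NM tag. ``on_error`` is 'raise' or 'skip'.
    """
    if dialect.upper() == "PAF":
        return _read_paf(Path(path), on_error)
    if dialect.upper() == "SAM":
        return _read_sam(Path(path), on_error)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_paf(path: Path, on_error: str) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                f = line.split("\t")
                cigar = None
                for tag in f[12:]:
                    if tag.startswith("cg:Z:"):
                        cigar = tag[5:]
                out.append(AlignmentRecord(
                    query_name=f[0], query_start=int(f[2]), query_end=int(f[3]),
                    query_len=int(f[1]), target_name=f[5],
                    target_start=int(f[7]), target_end=int(f[8]),
                    target_len=int(f[6]), strand=f[4],
                    matches=int(f[9]), aligned_columns=int(f[10]),
                    score=float(int(f[9])), cigar=cigar))
            except (ValueError, IndexError) as exc:
                if on_error == "raise":
                    raise ValueError(f"{path}:{lineno}: bad PAF line: {exc}") from exc
                logger.warning("%s:%d: skipping malformed PAF line (%s)",
                               path, lineno, exc)
    return out


def _read_sam(path: Path, on_error: str) -> list[AlignmentRecord]:
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            try:
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                matches, cols = cigar_matches(rec.cigarstring, nm)
                qlen = rec.query_length or rec.infer_read_length()
                qstart = rec.query_alignment_start
                qend = rec.query_alignment_end
                strand = "-" if rec.is_reverse else "+"
                if strand == "-":
                    qstart, qend = qlen - qend, qlen - qstart
                out.append(AlignmentRecord(
                    query_name=rec.query_name, query_start=qstart,
                    query_end=qend, query_len=qlen,
                    target_name=rec.reference_name,
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    target_len=sam.get_reference_length(rec.reference_name),
                    strand=strand, matches=matches, aligned_columns=cols,
                    score=float(matches), cigar=rec.cigarstring))
            except (ValueError, KeyError) as exc:
                if on_error == "raise":
                    raise
                logger.warning("%s: skipping SAM record %s (%s)",
                               path, rec.query_name, exc)
    return out


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            cols = [r.query_name, r.query_len, r.query_start, r.query_end,
                    r.strand, r.target_name, r.target_len, r.target_start,
                    r.target_end, r.matches, r.aligned_columns, 60]
            line = "\t".join(str(c) for c in cols)
            if r.cigar:
                line += f"\tcg:Z:{r.cigar}"
            fh.write(line + "\n")
    return path
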