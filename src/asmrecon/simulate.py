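"""Seeded synthetic-data generator and ground-truth harness.

Emulates the data regime of a reference-assembly upgrade project: a true
genome with interspersed repeats and segmental duplications; a derived
draft assembly with planted gaps (including wrongly-separated overlapping
contig ends, i.e. negative fills), collapsed duplications, misjoins and
small base errors; long-insert end pairs at a chosen physical coverage;
and shotgun reads with true placements, so every downstream module can be
scored exactly without an external mapper.

All randomness flows from one integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import Assembly, BedInterval, Scaffold, revcomp
from .polish import DEL, INS, SUB, EditOperation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RepeatFamily:
    name: str
    unit_len: int
    copies: int
    divergence: float = 0.1  # per-base substitution rate from consensus


@dataclass(frozen=True)
class DupSpec:
    length: int
    identity: float
    collapsed: bool = False  # derived assembly keeps only the source copy
    strand: str = "+"


@dataclass(frozen=True)
class GapPlan:
    count: int = 0
    fill_lo: int = 50       # true sequence replaced by each gap (bp)
    fill_hi: int = 2000
    n_len_lo: int = 50      # N-run length written into the assembly
    n_len_hi: int = 500
    neg_frac: float = 0.0   # fraction of gaps that are negative (overlap) gaps
    overlap_lo: int = 20
    overlap_hi: int = 200


@dataclass(frozen=True)
class MisjoinPlan:
    inversions: int = 0
    translocations: int = 0   # equal-length distant segment swaps
    seg_lo: int = 50_000
    seg_hi: int = 200_000


@dataclass(frozen=True)
class ErrorPlan:
    substitutions: int = 0
    indels: int = 0
    indel_max: int = 5
    extra_indel_lens: tuple[int, ...] = ()  # e.g. (6,) to plant boundary cases


@dataclass
class SimConfig:
    genome_len: int = 1_000_000
    gc_content: float = 0.41  # great-ape-like base composition
    n_scaffolds: int = 1
    repeats: list[RepeatFamily] = field(default_factory=list)
    duplications: list[DupSpec] = field(default_factory=list)
    gaps: GapPlan = field(default_factory=GapPlan)
    misjoins: MisjoinPlan = field(default_factory=MisjoinPlan)
    errors: ErrorPlan = field(default_factory=ErrorPlan)
    feature_margin: int = 3000  # minimum spacing between planted features
    seed: int = 0


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass(frozen=True)
class DupTruth:
    scaffold: str
    src: tuple[int, int]   # genome coords
    dst: tuple[int, int]
    identity: float
    strand: str
    collapsed: bool


@dataclass(frozen=True)
class GapSpec:
    """A planted gap in genome coordinates.

    fill_len > 0: genome[pos, pos+fill_len) is replaced by an N-run.
    fill_len < 0: nothing is lost; the assembly wrongly separates
    overlapping contig ends, duplicating genome[pos, pos-fill_len) on both
    sides of the N-run.
    """

    scaffold: str
    pos: int
    fill_len: int
    n_len: int


@dataclass
class GapTruth:
    scaffold: str          # derived assembly coords of the N-run
    start: int
    end: int
    fill_seq: str          # true sequence the gap replaces ('' if negative)
    fill_len: int          # signed


@dataclass(frozen=True)
class SegPiece:
    """Maps one derived-assembly segment back to the genome."""

    scaffold: str
    out_start: int
    out_end: int
    g_scaffold: str
    g_start: int
    g_end: int
    strand: str
    # planted-error adjustments inside this piece: after genome offset
    # err_offsets[i] (relative to g_start), derived coords shift by
    # err_cumdelta[i]
    err_offsets: tuple[int, ...] = ()
    err_cumdelta: tuple[int, ...] = ()


@dataclass
class GroundTruth:
    genome: Assembly
    gap_specs: list[GapSpec] = field(default_factory=list)
    gaps: list[GapTruth] = field(default_factory=list)
    errors: list[EditOperation] = field(default_factory=list)  # corrections
    junctions: list[tuple[str, int]] = field(default_factory=list)
    collapses: list[DupTruth] = field(default_factory=list)
    duplications: list[DupTruth] = field(default_factory=list)
    segments: list[SegPiece] = field(default_factory=list)

    def map_genome(self, scaffold: str, pos: int) -> tuple[str, int, str] | None:
        """Derived-assembly location of a genome base, or None if the base
        is absent from the derived assembly (gap fill). Collapsed-copy
        positions redirect to the retained copy."""
        for c in self.collapses:
            if c.scaffold == scaffold and c.dst[0] <= pos < c.dst[1]:
                off = pos - c.dst[0]
                if c.strand == "+":
                    pos = c.src[0] + off
                else:
                    pos = c.src[1] - 1 - off
                break
        for seg in self.segments:
            if seg.g_scaffold != scaffold or not seg.g_start <= pos < seg.g_end:
                continue
            off = pos - seg.g_start
            delta = 0
            if seg.err_offsets:
                import bisect
                i = bisect.bisect_right(seg.err_offsets, off) - 1
                if i >= 0:
                    delta = seg.err_cumdelta[i]
            if seg.strand == "+":
                return seg.scaffold, seg.out_start + off + delta, "+"
            return seg.scaffold, seg.out_end - 1 - off, "-"
        return None


# ---------------------------------------------------------------------------
# genome synthesis


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a
    different base), giving expected identity 1 - rate."""
    out = arr.copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


class _Placer:
    """Samples non-overlapping feature intervals with a safety margin."""

    def __init__(self, rng: np.random.Generator, scaffold_lens: dict[str, int],
                 margin: int):
        self.rng = rng
        self.lens = scaffold_lens
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {
            n: [] for n in scaffold_lens}

    def reserve(self, scaffold: str, start: int, end: int) -> None:
        self.occupied[scaffold].append((start - self.margin, end + self.margin))

    def place(self, length: int, scaffold: str | None = None,
              edge_margin: int | None = None, tries: int = 2000
              ) -> tuple[str, int]:
        edge = self.margin if edge_margin is None else edge_margin
        names = [scaffold] if scaffold else list(self.lens)
        weights = np.array([self.lens[n] for n in names], dtype=float)
        for _ in range(tries):
            name = names[self.rng.choice(len(names), p=weights / weights.sum())]
            hi = self.lens[name] - length - edge
            if hi <= edge:
                continue
            s = int(self.rng.integers(edge, hi))
            e = s + length
            if all(e + self.margin <= os or s - self.margin >= oe
                   for os, oe in self.occupied[name]):
                self.reserve(name, s, e)
                return name, s
        raise ValueError(f"could not place a {length} bp feature; "
                         f"features exceed genome capacity")


@dataclass
class GenomeFeatures:
    repeats: list[BedInterval]
    duplications: list[DupTruth]


def make_genome(cfg: SimConfig) -> tuple[Assembly, GenomeFeatures]:
    """Synthesize a genome with planted repeats and segmental duplications.

    Repeat copies diverge from a family consensus by per-base substitution;
    duplication copies are written at a second locus mutated to the target
    identity. Deterministic under cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    per = cfg.genome_len // cfg.n_scaffolds
    seqs = {f"chr{i + 1}": _random_seq(rng, per, cfg.gc_content)
            for i in range(cfg.n_scaffolds)}
    placer = _Placer(rng, {n: len(s) for n, s in seqs.items()},
                     cfg.feature_margin)
    repeats: list[BedInterval] = []
    for fam in cfg.repeats:
        consensus = _random_seq(rng, fam.unit_len, cfg.gc_content)
        for _ in range(fam.copies):
            name, s = placer.place(fam.unit_len)
            seqs[name][s:s + fam.unit_len] = _mutate(rng, consensus,
                                                     fam.divergence)
            repeats.append(BedInterval(name, s, s + fam.unit_len, fam.name))
    dups: list[DupTruth] = []
    for spec in cfg.duplications:
        src_name, src_s = placer.place(spec.length)
        dst_name, dst_s = placer.place(spec.length, scaffold=src_name)
        copy = _mutate(rng, seqs[src_name][src_s:src_s + spec.length],
                       1.0 - spec.identity)
        if spec.strand == "-":
            lut = np.zeros(256, dtype=np.uint8)
            for a, b in zip(b"ACGT", b"TGCA"):
                lut[a] = b
            copy = lut[copy][::-1]
        seqs[dst_name][dst_s:dst_s + spec.length] = copy
        dups.append(DupTruth(src_name, (src_s, src_s + spec.length),
                             (dst_s, dst_s + spec.length), spec.identity,
                             spec.strand, spec.collapsed))
    scaffolds = [Scaffold(n, s.tobytes().decode("ascii"))
                 for n, s in seqs.items()]
    return Assembly("genome", scaffolds), GenomeFeatures(repeats, dups)


# ---------------------------------------------------------------------------
# piece table for deriving an assembly


@dataclass
class _Piece:
    kind: str                      # 'seq' or 'N'
    g_scaffold: str = ""
    g_start: int = 0
    g_end: int = 0
    strand: str = "+"
    n_len: int = 0
    gap_truth: dict | None = None
    junction_before: bool = False
    errors: list = field(default_factory=list)  # (offset, kind, payload)

    @property
    def length(self) -> int:
        return self.n_len if self.kind == "N" else self.g_end - self.g_start

    def split(self, k: int) -> tuple["_Piece", "_Piece"]:
        assert 0 < k < self.length and self.kind == "seq"
        if self.strand == "+":
            a = _Piece("seq", self.g_scaffold, self.g_start, self.g_start + k,
                       "+", junction_before=self.junction_before)
            b = _Piece("seq", self.g_scaffold, self.g_start + k, self.g_end, "+")
        else:
            a = _Piece("seq", self.g_scaffold, self.g_end - k, self.g_end,
                       "-", junction_before=self.junction_before)
            b = _Piece("seq", self.g_scaffold, self.g_start, self.g_end - k, "-")
        return a, b


class _PieceTable:
    def __init__(self, g_scaffold: str, g_len: int):
        self.pieces: list[_Piece] = [_Piece("seq", g_scaffold, 0, g_len, "+")]

    def _boundary(self, pos: int) -> int:
        """Ensure a piece boundary at derived coordinate pos; return index."""
        off = 0
        for i, p in enumerate(self.pieces):
            if off == pos:
                return i
            if off + p.length > pos:
                a, b = p.split(pos - off)
                self.pieces[i:i + 1] = [a, b]
                return i + 1
            off += p.length
        return len(self.pieces)

    def delete(self, start: int, end: int) -> None:
        i = self._boundary(start)
        j = self._boundary(end)
        del self.pieces[i:j]

    def invert(self, start: int, end: int) -> None:
        i = self._boundary(start)
        j = self._boundary(end)
        block = self.pieces[i:j][::-1]
        for p in block:
            p.strand = "-" if p.strand == "+" else "+"
            p.junction_before = False
        if block:
            block[0].junction_before = True
        self.pieces[i:j] = block
        if i + len(block) < len(self.pieces):
            self.pieces[i + len(block)].junction_before = True

    def swap(self, a0: int, a1: int, b0: int, b1: int) -> None:
        """Exchange two equal-length disjoint segments (a before b)."""
        assert a1 - a0 == b1 - b0 and a1 <= b0
        i0 = self._boundary(a0); i1 = self._boundary(a1)
        j0 = self._boundary(b0); j1 = self._boundary(b1)
        block_a = self.pieces[i0:i1]
        block_b = self.pieces[j0:j1]
        for blk in (block_a, block_b):
            for p in blk:
                p.junction_before = False
            if blk:
                blk[0].junction_before = True
        self.pieces[j0:j1] = block_a
        self.pieces[i0:i1] = block_b
        for idx in (i0 + len(block_b), j0 + len(block_a)):
            if idx < len(self.pieces):
                self.pieces[idx].junction_before = True

    def plant_gap(self, start: int, fill_len: int, n_len: int,
                  fill_seq: str, overlap: int = 0) -> None:
        """fill_len > 0: replace derived [start, start+fill_len) with Ns.
        fill_len < 0 (overlap = -fill_len): duplicate the overlap on both
        sides of the N-run."""
        if fill_len > 0:
            i = self._boundary(start)
            j = self._boundary(start + fill_len)
            gap = _Piece("N", n_len=n_len,
                         gap_truth={"fill_seq": fill_seq, "fill_len": fill_len})
            self.pieces[i:j] = [gap]
        else:
            o = overlap
            i = self._boundary(start + o)
            left = self.pieces[i - 1]
            assert left.kind == "seq" and left.strand == "+"
            dup = _Piece("seq", left.g_scaffold, left.g_end - o, left.g_end, "+")
            gap = _Piece("N", n_len=n_len,
                         gap_truth={"fill_seq": "", "fill_len": fill_len})
            self.pieces[i:i] = [gap, dup]


# ---------------------------------------------------------------------------
# derive


def derive_assembly(genome: Assembly, cfg: SimConfig,
                    features: GenomeFeatures | None = None,
                    gap_specs: list[GapSpec] | None = None,
                    ) -> tuple[Assembly, GroundTruth]:
    """Derive a draft assembly from the genome with planted defects.

    Plants, in genome coordinates chosen disjoint with a safety margin:
    collapsed duplications (the second copy is dropped), misjoins
    (inversions and equal-length segment swaps), gaps per ``cfg.gaps`` (or
    the explicit ``gap_specs``), and small errors per ``cfg.errors``.
    Returns the assembly plus a GroundTruth sufficient to score every
    downstream module exactly.
    """
    rng = np.random.default_rng((cfg.seed * 2654435761 + 1) % 2**31)
    features = features or GenomeFeatures([], [])
    truth = GroundTruth(genome=genome)
    placer = _Placer(rng, {s.name: len(s) for s in genome},
                     cfg.feature_margin)
    for iv in features.repeats:
        placer.reserve(iv.chrom, iv.start, iv.end)
    for d in features.duplications:
        placer.reserve(d.scaffold, *d.src)
        placer.reserve(d.scaffold, *d.dst)

    ops: list[tuple[int, str, tuple]] = []  # (max genome coord, kind, args)

    for d in features.duplications:
        if d.collapsed:
            ops.append((d.dst[1], "collapse", (d,)))
            truth.collapses.append(d)
        truth.duplications.append(d)

    mj = cfg.misjoins
    for _ in range(mj.inversions):
        length = int(rng.integers(mj.seg_lo, mj.seg_hi + 1))
        name, s = placer.place(length)
        ops.append((s + length, "invert", (name, s, s + length)))
    for _ in range(mj.translocations):
        length = int(rng.integers(mj.seg_lo, mj.seg_hi + 1))
        name, a = placer.place(length)
        name2, b = placer.place(length, scaffold=name)
        a0, b0 = sorted((a, b))
        ops.append((b0 + length, "swap",
                    (name, a0, a0 + length, b0, b0 + length)))

    if gap_specs is None:
        gap_specs = plan_gaps(cfg.gaps, placer, rng)
    else:
        for g in gap_specs:
            placer.reserve(g.scaffold, g.pos, g.pos + max(g.fill_len, -g.fill_len))
    truth.gap_specs = list(gap_specs)
    for g in gap_specs:
        hi = g.pos + (g.fill_len if g.fill_len > 0 else -g.fill_len)
        ops.append((hi, "gap", (g,)))

    # errors use a tight margin of their own (they are point features) but
    # still respect every already-reserved feature window
    err_placer = _Placer(rng, {s.name: len(s) for s in genome}, margin=30)
    for scaf_name, occ in placer.occupied.items():
        err_placer.occupied[scaf_name].extend(occ)
    err_plan = _plan_errors(cfg.errors, err_placer, rng, genome)

    # apply ops at descending genome coordinate: every op's own interval
    # is still at its genome coordinates when it is applied
    tables = {s.name: _PieceTable(s.name, len(s)) for s in genome}
    for _, kind, args in sorted(ops, key=lambda t: -t[0]):
        if kind == "collapse":
            d = args[0]
            tables[d.scaffold].delete(*d.dst)
        elif kind == "invert":
            name, s, e = args
            tables[name].invert(s, e)
            # junction truth comes from piece flags at render time
        elif kind == "swap":
            name, a0, a1, b0, b1 = args
            tables[name].swap(a0, a1, b0, b1)
        elif kind == "gap":
            g = args[0]
            scaf = genome[g.scaffold]
            if g.fill_len > 0:
                fill = scaf.sequence[g.pos:g.pos + g.fill_len]
                tables[g.scaffold].plant_gap(g.pos, g.fill_len, g.n_len, fill)
            else:
                tables[g.scaffold].plant_gap(g.pos, g.fill_len, g.n_len, "",
                                             overlap=-g.fill_len)

    _attach_errors(tables, err_plan)
    derived = _render(genome, tables, truth, "derived", rng)
    return derived, truth


def plan_gaps(plan: GapPlan, placer: _Placer,
              rng: np.random.Generator) -> list[GapSpec]:
    specs: list[GapSpec] = []
    for _ in range(plan.count):
        negative = rng.random() < plan.neg_frac
        if negative:
            o = int(rng.integers(plan.overlap_lo, plan.overlap_hi + 1))
            name, s = placer.place(2 * o)  # reserve room for the overlap dup
            n_len = int(rng.integers(plan.n_len_lo, plan.n_len_hi + 1))
            specs.append(GapSpec(name, s, -o, n_len))
        else:
            f = int(rng.integers(plan.fill_lo, plan.fill_hi + 1))
            name, s = placer.place(f)
            n_len = int(rng.integers(plan.n_len_lo, plan.n_len_hi + 1))
            specs.append(GapSpec(name, s, f, n_len))
    return specs


def _plan_errors(plan: ErrorPlan, placer: _Placer, rng: np.random.Generator,
                 genome: Assembly) -> dict[str, list[tuple[int, str, int]]]:
    """Plan (genome_pos, kind, length) errors, margin-separated from every
    other feature. kind: 'sub', 'ins' (assembly gained bases), 'del'
    (assembly lost bases)."""
    out: dict[str, list[tuple[int, str, int]]] = {s.name: [] for s in genome}
    def plant(kind: str, length: int) -> None:
        # reserve a small window so errors never collide with anything
        name, s = placer.place(max(length, 1) + 20)
        out[name].append((s + 10, kind, length))
    for _ in range(plan.substitutions):
        plant("sub", 1)
    for _ in range(plan.indels):
        length = int(rng.integers(1, plan.indel_max + 1))
        plant("ins" if rng.random() < 0.5 else "del", length)
    for length in plan.extra_indel_lens:
        plant("ins" if rng.random() < 0.5 else "del", length)
    for name in out:
        out[name].sort()
    return out


def _attach_errors(tables: dict[str, _PieceTable],
                   err_plan: dict[str, list[tuple[int, str, int]]]) -> None:
    for name, errors in err_plan.items():
        if not errors:
            continue
        for p in tables[name].pieces:
            if p.kind != "seq" or p.strand != "+":
                continue
            for g, kind, length in errors:
                if p.g_start <= g and g + (length if kind == "del" else 1) \
                        <= p.g_end:
                    p.errors.append((g - p.g_start, kind, length))
        # errors planned in deleted regions (none, by margin) are dropped


def _render(genome: Assembly, tables: dict[str, _PieceTable],
            truth: GroundTruth, name: str,
            rng: np.random.Generator) -> Assembly:
    scaffolds = []
    for g_scaf in genome:
        table = tables[g_scaf.name]
        parts: list[str] = []
        out = 0
        for p in table.pieces:
            if p.junction_before:
                truth.junctions.append((g_scaf.name, out))
            if p.kind == "N":
                parts.append("N" * p.n_len)
                truth.gaps.append(GapTruth(g_scaf.name, out, out + p.n_len,
                                           p.gap_truth["fill_seq"],
                                           p.gap_truth["fill_len"]))
                out += p.n_len
                continue
            src = genome[p.g_scaffold].sequence[p.g_start:p.g_end]
            content = revcomp(src) if p.strand == "-" else src
            if p.errors:
                content, seg = _apply_piece_errors(
                    g_scaf.name, out, p, content, truth, rng)
            else:
                seg = SegPiece(g_scaf.name, out, out + len(content),
                               p.g_scaffold, p.g_start, p.g_end, p.strand)
            truth.segments.append(seg)
            parts.append(content)
            out += len(content)
        scaffolds.append(Scaffold(g_scaf.name, "".join(parts)))
    return Assembly(name, scaffolds)


def _apply_piece_errors(scaffold: str, out_start: int, piece: _Piece,
                        content: str, truth: GroundTruth,
                        rng: np.random.Generator) -> tuple[str, SegPiece]:
    """Introduce planted errors into a forward piece, recording the
    corrections (in final derived coordinates) and the offset map."""
    chunks: list[str] = []
    offsets: list[int] = []
    cumdelta: list[int] = []
    pos = 0
    delta = 0
    for off, kind, length in sorted(piece.errors):
        chunks.append(content[pos:off])
        final = out_start + off + delta
        if kind == "sub":
            old = content[off]
            new = "ACGT".replace(old, "")[rng.integers(3)]
            chunks.append(new)
            truth.errors.append(EditOperation(scaffold, final, SUB, new, old))
            pos = off + 1
        elif kind == "ins":
            gained = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            chunks.append(gained)
            truth.errors.append(EditOperation(scaffold, final, DEL, gained, ""))
            chunks.append(content[off:off + 1])
            pos = off + 1
            delta += length
            offsets.append(off)
            cumdelta.append(delta)
        else:  # del: assembly lost `length` bases starting at off
            lost = content[off:off + length]
            truth.errors.append(EditOperation(scaffold, final, INS, "", lost))
            pos = off + length
            delta -= length
            offsets.append(off + length)
            cumdelta.append(delta)
    chunks.append(content[pos:])
    new_content = "".join(chunks)
    seg = SegPiece(scaffold, out_start, out_start + len(new_content),
                   piece.g_scaffold, piece.g_start, piece.g_end, piece.strand,
                   tuple(offsets), tuple(cumdelta))
    return new_content, seg


# ---------------------------------------------------------------------------
# end pairs


@dataclass(frozen=True)
class SimulatedEndPair:
    pair_id: str
    scaffold_a: str | None
    pos_a: int | None      # leftmost coordinate of end A on the assembly
    strand_a: str | None
    scaffold_b: str | None
    pos_b: int | None
    strand_b: str | None
    end_len: int
    is_chimera: bool
    true_insert: int


def simulate_end_pairs(genome: Assembly, truth: GroundTruth | None,
                       insert_mean: float = 40_000.0,
                       insert_sd: float = 4_000.0,
                       phys_coverage: float = 6.0,
                       chimera_rate: float = 0.0,
                       end_len: int = 600,
                       seed: int = 0) -> list[SimulatedEndPair]:
    """Draw long-insert end pairs from the genome and report their mapped
    positions on the derived assembly (via ground truth) or on the genome
    itself when ``truth`` is None.

    The pair count is round(phys_coverage * genome_len / insert_mean); the
    insert is Normal(mean, sd) truncated to at least 2*end_len + 1. A
    chimera joins its B end to a uniformly random locus and orientation.
    """
    rng = np.random.default_rng(seed)
    scaffolds = list(genome)
    lens = np.array([len(s) for s in scaffolds], dtype=float)
    total = lens.sum()
    n_pairs = int(round(phys_coverage * total / insert_mean))
    pairs: list[SimulatedEndPair] = []
    for i in range(n_pairs):
        si = int(rng.choice(len(scaffolds), p=lens / total))
        scaf = scaffolds[si]
        insert = int(max(2 * end_len + 1,
                         round(rng.normal(insert_mean, insert_sd))))
        if insert >= len(scaf):
            continue
        s = int(rng.integers(0, len(scaf) - insert))
        a = (scaf.name, s, s + end_len, "+")
        chim = rng.random() < chimera_rate
        if chim:
            sj = int(rng.choice(len(scaffolds), p=lens / total))
            other = scaffolds[sj]
            t = int(rng.integers(0, len(other) - end_len))
            b = (other.name, t, t + end_len,
                 "+" if rng.random() < 0.5 else "-")
        else:
            b = (scaf.name, s + insert - end_len, s + insert, "-")
        ma = _map_end(truth, a)
        mb = _map_end(truth, b)
        pairs.append(SimulatedEndPair(
            f"pair{i}",
            *(ma if ma else (None, None, None)),
            *(mb if mb else (None, None, None)),
            end_len=end_len, is_chimera=chim, true_insert=insert))
    return pairs


def _map_end(truth: GroundTruth | None, end: tuple[str, int, int, str],
             tol: int = 0) -> tuple[str, int, str] | None:
    """Derived placement of a genome interval; ``tol`` allows the mapped
    span to deviate from the interval length by up to that many bp (reads
    crossing planted indel errors), to be resolved by re-alignment."""
    name, s, e, strand = end
    if truth is None:
        return name, s, strand
    m1 = truth.map_genome(name, s)
    m2 = truth.map_genome(name, e - 1)
    if m1 is None or m2 is None or m1[0] != m2[0] or m1[2] != m2[2]:
        return None
    if m1[2] == "+":
        if abs((m2[1] - m1[1]) - (e - 1 - s)) > tol:
            return None
        return m1[0], m1[1], strand
    if abs((m1[1] - m2[1]) - (e - 1 - s)) > tol:
        return None
    return m1[0], m2[1], ("-" if strand == "+" else "+")


def write_end_pairs_tsv(pairs: Iterable[SimulatedEndPair],
                        path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("pairId\tscaffoldA\tposA\tstrandA\t"
                 "scaffoldB\tposB\tstrandB\tendLen\n")
        for p in pairs:
            fh.write("\t".join(str(x) if x is not None else "."
                               for x in (p.pair_id, p.scaffold_a, p.pos_a,
                                         p.strand_a, p.scaffold_b, p.pos_b,
                                         p.strand_b, p.end_len)) + "\n")
    return path


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class ReadPlacement:
    name: str
    scaffold: str       # on the placement target (derived assembly)
    start: int
    end: int
    strand: str
    seq: str            # oriented to the placement target's forward strand
    cigar: str
    nm: int
    identity: float


def simulate_reads(genome: Assembly, truth: GroundTruth | None,
                   target: Assembly | None = None,
                   coverage: float = 10.0, read_len: int = 100,
                   sub_rate: float = 0.0, seed: int = 0,
                   refine: bool = False) -> list[ReadPlacement]:
    """Uniformly sample reads from the genome and emit true placements.

    ``target`` is the assembly the placements refer to (the derived
    assembly when ``truth`` maps into one; the genome itself when both are
    None/omitted). With ``refine`` each placement is re-aligned (edlib)
    against the local target window, which yields exact CIGARs across
    planted indel errors — required for polishing fixtures. Reads whose
    placement cannot be resolved (ends in gaps or across piece boundaries)
    are dropped.
    """
    rng = np.random.default_rng(seed)
    scaffolds = list(genome)
    lens = np.array([len(s) for s in scaffolds], dtype=float)
    p_scaf = lens / lens.sum()
    total = int(lens.sum())
    n_reads = math.ceil(coverage * total / read_len)
    target_seqs = ({s.name: s.sequence for s in target}
                   if target is not None else None)
    scaf_idx = rng.choice(len(scaffolds), size=n_reads, p=p_scaf)
    u_start = rng.random(n_reads)
    placements: list[ReadPlacement] = []
    for i in range(n_reads):
        scaf = scaffolds[int(scaf_idx[i])]
        if len(scaf) <= read_len:
            continue
        s = int(u_start[i] * (len(scaf) - read_len))
        seq = scaf.sequence[s:s + read_len]
        if sub_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(read_len) < sub_rate)
            for h in hits:
                cur = chr(arr[h])
                arr[h] = ord("ACGT".replace(cur, "")[rng.integers(3)])
            seq = arr.tobytes().decode()
        m = _map_end(truth, (scaf.name, s, s + read_len, "+"),
                     tol=15 if refine else 0)
        if m is None:
            continue
        d_name, d_pos, d_strand = m
        oriented = seq if d_strand == "+" else revcomp(seq)
        placement = _finish_placement(target_seqs, f"read{i}", d_name, d_pos,
                                      oriented, read_len, refine)
        if placement is not None:
            placements.append(placement)
    placements.sort(key=lambda p: (p.scaffold, p.start))
    return placements


def _finish_placement(target_seqs: dict[str, str] | None, name: str,
                      d_name: str, d_pos: int, oriented: str, read_len: int,
                      refine: bool) -> ReadPlacement | None:
    import edlib

    from .align import edlib_stats

    if target_seqs is None:
        # placement on the genome itself: exact by construction
        return ReadPlacement(name, d_name, d_pos, d_pos + read_len, "+",
                             oriented, f"{read_len}=", 0, 1.0)
    tseq = target_seqs[d_name]
    if not refine:
        window = tseq[d_pos:d_pos + read_len]
        if len(window) < read_len or "N" in window:
            return None
        mism = sum(1 for a, b in zip(oriented, window) if a != b)
        return ReadPlacement(name, d_name, d_pos, d_pos + read_len, "+",
                             oriented, f"{read_len}M", mism,
                             1.0 - mism / read_len)
    pad = 16
    lo = max(0, d_pos - pad)
    hi = min(len(tseq), d_pos + read_len + pad)
    window = tseq[lo:hi]
    if "N" in window:
        return None
    res = edlib.align(oriented, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    l0, l1 = res["locations"][0]
    matches, cols = edlib_stats(res["cigar"])
    return ReadPlacement(name, d_name, lo + l0, lo + l1 + 1, "+", oriented,
                         res["cigar"], res["editDistance"],
                         matches / cols)


def write_sam(placements: Iterable[ReadPlacement], target: Assembly,
              path: str | Path) -> Path:
    """Write placements as a coordinate-sorted plain-text SAM file."""
    path = Path(path)
    order = {s.name: i for i, s in enumerate(target)}
    placements = sorted(placements, key=lambda p: (order[p.scaffold], p.start))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for s in target:
            fh.write(f"@SQ\tSN:{s.name}\tLN:{len(s)}\n")
        for p in placements:
            flag = 0 if p.strand == "+" else 16
            fh.write(f"{p.name}\t{flag}\t{p.scaffold}\t{p.start + 1}\t60\t"
                     f"{p.cigar}\t*\t0\t0\t{p.seq}\t*\tNM:i:{p.nm}\n")
    return path
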