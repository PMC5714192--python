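"""Pileup-consensus correction of residual small assembly errors.

Re-mapped read evidence is piled up per site; near-fixed discrepancies
(substitutions and indels strictly shorter than 6 bp) with sufficient depth
and allele support are integrated back into the assembly. Heterozygous-like
sites (support around 0.5) are deliberately left alone: the assembly is a
haploid mosaic and only near-fixed discrepancies qualify as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .core import Assembly, ToolConfig, gap_census

SUB, INS, DEL = "SUB", "INS", "DEL"


@dataclass(frozen=True)
class EditOperation:
    """One correction to the assembly, 0-based on the input assembly.

    SUB: replace ``ref`` (same length as ``alt``) at ``position``.
    DEL: remove ``ref`` starting at ``position`` (alt empty).
    INS: insert ``alt`` before ``position`` (ref empty).
    """

    scaffold: str
    position: int
    type: str
    ref: str
    alt: str
    support: float = 1.0
    depth: int = 0

    def __post_init__(self) -> None:
        if self.type == SUB and len(self.ref) != len(self.alt):
            raise ValueError("SUB alleles must have equal length")
        if self.type == INS and self.ref:
            raise ValueError("INS has empty ref")
        if self.type == DEL and self.alt:
            raise ValueError("DEL has empty alt")

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)

    def footprint(self) -> tuple[int, int]:
        """Half-open interval of assembly bases this edit touches."""
        return self.position, self.position + len(self.ref)


@dataclass
class SiteEvidence:
    scaffold: str
    position: int
    ref_base: str
    depth: int
    allele_counts: dict = field(default_factory=dict)
    # alleles: ('S', base) substitution; ('I', seq) insertion before this
    # site; ('D', seq) deletion starting here; ('R',) reference-agreeing


class PileupData:
    """Per-scaffold depth and sparse non-reference allele counts."""

    def __init__(self, asm: Assembly, cfg: ToolConfig):
        self.asm = asm
        self.cfg = cfg
        self.depth: dict[str, np.ndarray] = {
            s.name: np.zeros(len(s), dtype=np.int32) for s in asm}
        self.ref_count: dict[str, np.ndarray] = {
            s.name: np.zeros(len(s), dtype=np.int32) for s in asm}
        self.ref_arr: dict[str, np.ndarray] = {
            s.name: np.frombuffer(s.sequence.encode("ascii"), dtype=np.uint8)
            for s in asm}
        self.alts: dict[str, dict[int, dict[tuple, int]]] = {
            s.name: {} for s in asm}
        # (read_serial, position, signed length) of every indel op seen,
        # for the per-read net-discrepancy guard in call_edits
        self.indel_events: dict[str, list[tuple[int, int, int]]] = {
            s.name: [] for s in asm}
        self._read_serial = 0
        self.guard: dict[str, np.ndarray] = {}
        for s in asm:
            mask = np.zeros(len(s), dtype=bool)
            for g in gap_census(Assembly("x", [s]), cfg.min_gap_len):
                lo = max(0, g.start - cfg.guard_bp)
                hi = min(len(s), g.end + cfg.guard_bp)
                mask[lo:hi] = True
            self.guard[s.name] = mask

    def add_alt(self, scaf: str, pos: int, allele: tuple, n: int = 1) -> None:
        self.alts[scaf].setdefault(pos, {})
        self.alts[scaf][pos][allele] = self.alts[scaf][pos].get(allele, 0) + n

    def sites(self) -> Iterator[SiteEvidence]:
        """Yield evidence for every covered, non-guarded site."""
        for scaf in self.asm:
            name = scaf.name
            depth = self.depth[name]
            refc = self.ref_count[name]
            guard = self.guard[name]
            alts = self.alts[name]
            covered = np.flatnonzero((depth > 0) & ~guard)
            for pos in covered.tolist():
                counts = dict(alts.get(pos, {}))
                counts[("R",)] = int(refc[pos])
                yield SiteEvidence(name, pos, scaf.sequence[pos],
                                   int(depth[pos]), counts)


def pileup_sites(sam_path: str | Path, asm: Assembly,
                 cfg: ToolConfig | None = None) -> PileupData:
    """Accumulate per-site allele evidence from a sorted SAM file.

    Sites within ``guard_bp`` of a gap edge are masked out. Match columns
    are compared against the assembly base, so plain-M CIGARs work as well
    as extended =/X ones.
    """
    import pysam

    cfg = cfg or ToolConfig()
    pile = PileupData(asm, cfg)
    last: tuple[str, int] | None = None
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            key = (rec.reference_name, rec.reference_start)
            if last is not None and rec.reference_name == last[0] and key[1] < last[1]:
                raise ValueError("input SAM is not coordinate-sorted")
            last = key
            _accumulate(pile, rec)
    return pile


def _accumulate(pile: PileupData, rec) -> None:
    scaf = pile.asm[rec.reference_name]
    ref_seq = scaf.sequence
    depth = pile.depth[scaf.name]
    refc = pile.ref_count[scaf.name]
    read = rec.query_sequence
    rpos = rec.reference_start
    qpos = 0
    pile._read_serial += 1
    serial = pile._read_serial
    for op, n in rec.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            seg = read[qpos:qpos + n]
            depth[rpos:rpos + n] += 1
            a = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
            b = pile.ref_arr[scaf.name][rpos:rpos + n]
            mism = np.flatnonzero(a != b)
            refc[rpos:rpos + n] += 1
            if len(mism):
                refc[rpos + mism] -= 1
                for i in mism.tolist():
                    pile.add_alt(scaf.name, rpos + i, ("S", seg[i]))
            rpos += n
            qpos += n
        elif op == 1:  # I: insertion before reference position rpos
            pile.add_alt(scaf.name, rpos, ("I", read[qpos:qpos + n]))
            pile.indel_events[scaf.name].append((serial, rpos, n))
            qpos += n
        elif op in (2, 3):  # D/N: deletion anchored at first deleted base
            pile.add_alt(scaf.name, rpos, ("D", ref_seq[rpos:rpos + n]))
            pile.indel_events[scaf.name].append((serial, rpos, -n))
            depth[rpos:rpos + n] += 1
            rpos += n
        elif op == 4:  # S
            qpos += n
        # H/P consume nothing we track


def call_edits(sites: Iterable[SiteEvidence] | PileupData,
               cfg: ToolConfig | None = None) -> list[EditOperation]:
    """Emit an edit where the top non-reference allele is near-fixed.

    Requires depth >= min_depth, support >= min_allele_frac, more support
    than the reference allele (ties break toward no edit), and indel length
    <= max_indel_edit (i.e. strictly < 6 bp).
    """
    cfg = cfg or ToolConfig()
    indel_events = None
    if isinstance(sites, PileupData):
        indel_events = sites.indel_events
        sites = sites.sites()
    locus = _LocusSupport(indel_events)
    candidates: list[EditOperation] = []
    for site in sites:
        if site.depth < cfg.min_depth:
            continue
        best = None
        for allele, count in site.allele_counts.items():
            if allele == ("R",):
                continue
            if best is None or count > best[1]:
                best = (allele, count)
        if best is None:
            continue
        allele, count = best
        kind, payload = allele[0], allele[1] if len(allele) > 1 else ""
        if kind == "S":
            # substitutions compete directly with the reference base
            if count / site.depth < cfg.min_allele_frac \
                    or count <= site.allele_counts.get(("R",), 0):
                continue
            support = count / site.depth
        elif locus.available:
            # reads fragment one indel into several equivalent aligned
            # representations (shifted anchors, split ops), so candidacy
            # uses locus support: the fraction of spanning reads carrying
            # any indel nearby, with the allele backed by at least half
            # of those carriers
            carriers = locus.carriers(site.scaffold, site.position,
                                      len(payload))
            support = carriers / site.depth
            if support < cfg.min_allele_frac or count < 0.5 * carriers:
                continue
        else:
            if count / site.depth < cfg.min_allele_frac \
                    or (kind == "D"
                        and count <= site.allele_counts.get(("R",), 0)):
                continue
            support = count / site.depth
        if kind == "S":
            candidates.append(EditOperation(site.scaffold, site.position,
                                            SUB, site.ref_base, payload,
                                            support, site.depth))
        elif kind == "I":
            candidates.append(EditOperation(site.scaffold, site.position,
                                            INS, "", payload, support,
                                            site.depth))
        else:
            candidates.append(EditOperation(site.scaffold, site.position,
                                            DEL, payload, "", support,
                                            site.depth))
    return _apply_indel_length_rule(candidates, cfg, indel_events)


class _LocusSupport:
    """Distinct-read indel carrier counts near a position, from the
    pileup's per-read indel events."""

    def __init__(self, indel_events: dict | None):
        self.available = indel_events is not None
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if indel_events:
            for scaf, events in indel_events.items():
                if not events:
                    continue
                arr = np.array(events, dtype=np.int64)
                order = np.argsort(arr[:, 1], kind="stable")
                self._sorted[scaf] = (arr[order, 1], arr[order, 0])

    def carriers(self, scaffold: str, position: int, allele_len: int,
                 pad: int = 10) -> int:
        if scaffold not in self._sorted:
            return 0
        pos, serial = self._sorted[scaffold]
        lo = np.searchsorted(pos, position - pad, side="left")
        hi = np.searchsorted(pos, position + allele_len + pad, side="right")
        return len(np.unique(serial[lo:hi]))


def _apply_indel_length_rule(candidates: list[EditOperation],
                             cfg: ToolConfig,
                             indel_events: dict | None = None
                             ) -> list[EditOperation]:
    """Enforce the strict <6 bp indel rule on the *net local discrepancy*.

    Alignment can fragment one larger indel into adjacent smaller ops
    (e.g. 6 bp split as 2+4 around a coincidentally matching base), so
    indel candidates within 10 bp of each other are grouped and the whole
    group is dropped when its net length change — or any single member —
    exceeds max_indel_edit. When per-read indel events are available the
    locus discrepancy is additionally measured as the median net indel
    content of the reads spanning the group, which sees the full size of
    a large indel even when no single aligned op does. Substitutions are
    unaffected.
    """
    out = [e for e in candidates if e.type == SUB]
    indels = sorted((e for e in candidates if e.type != SUB),
                    key=lambda e: (e.scaffold, e.position))
    group: list[EditOperation] = []
    for e in indels + [None]:
        if group and (e is None or e.scaffold != group[-1].scaffold
                      or e.position - group[-1].footprint()[1] > 10):
            net = sum(g.length_delta for g in group)
            longest = max(max(len(g.ref), len(g.alt)) for g in group)
            if abs(net) <= cfg.max_indel_edit \
                    and longest <= cfg.max_indel_edit \
                    and abs(_per_read_net(group, indel_events)) \
                    <= cfg.max_indel_edit:
                out.extend(group)
            group = []
        if e is not None:
            group.append(e)
    return sorted(out, key=lambda e: (e.scaffold, e.position))


def _per_read_net(group: list[EditOperation],
                  indel_events: dict | None) -> float:
    """Median over reads of the net indel bp each read reports within the
    group's local window (0 when event data is unavailable)."""
    if not indel_events:
        return 0.0
    scaf = group[0].scaffold
    lo = min(e.position for e in group) - 10
    hi = max(e.footprint()[1] for e in group) + 10
    per_read: dict[int, int] = {}
    for serial, pos, delta in indel_events.get(scaf, ()):
        if lo <= pos <= hi:
            per_read[serial] = per_read.get(serial, 0) + delta
    if not per_read:
        return 0.0
    return float(np.median(list(per_read.values())))


def integrate_edits(asm: Assembly, edits: Iterable[EditOperation]
                    ) -> tuple[Assembly, dict]:
    """Apply edits (right-to-left per scaffold, so coordinates stay valid).

    Overlapping edits: the higher-support one is kept, the other logged in
    the report. Returns the edited assembly and a count report by type.
    """
    by_scaf: dict[str, list[EditOperation]] = {}
    for e in edits:
        by_scaf.setdefault(e.scaffold, []).append(e)
    report = {"SUB": 0, "INS": 0, "DEL": 0, "conflicts": 0,
              "bases_changed": 0, "applied": []}
    new_scaffolds = []
    for scaf in asm:
        todo = sorted(by_scaf.get(scaf.name, []),
                      key=lambda e: (e.position, -e.support))
        kept: list[EditOperation] = []
        for e in todo:
            if kept and _overlaps(kept[-1], e):
                report["conflicts"] += 1
                if e.support > kept[-1].support:
                    kept[-1] = e
                continue
            kept.append(e)
        seq = scaf.sequence
        for e in reversed(kept):
            s, t = e.footprint()
            if seq[s:t] != e.ref:
                raise ValueError(
                    f"edit ref mismatch at {scaf.name}:{e.position} "
                    f"(expected {e.ref!r}, found {seq[s:t]!r})")
            seq = seq[:s] + e.alt + seq[t:]
            report[e.type] += 1
            report["bases_changed"] += max(len(e.ref), len(e.alt))
            report["applied"].append(e)
        new_scaffolds.append(type(scaf)(scaf.name, seq))
    return Assembly(asm.name, new_scaffolds), report


def _overlaps(a: EditOperation, b: EditOperation) -> bool:
    a0, a1 = a.footprint()
    b0, b1 = b.footprint()
    if a1 == a0 and b1 == b0:
        return a0 == b0
    return max(a0, b0) < min(a1, b1)


def invert_edits(edits: Iterable[EditOperation]) -> list[EditOperation]:
    """Edits that undo ``edits`` on the already-edited assembly.

    Coordinates are shifted by the cumulative length change of every edit
    to the left; SUB inverts in place, INS becomes DEL and vice versa.
    """
    out: list[EditOperation] = []
    by_scaf: dict[str, list[EditOperation]] = {}
    for e in edits:
        by_scaf.setdefault(e.scaffold, []).append(e)
    for scaf, todo in by_scaf.items():
        delta = 0
        for e in sorted(todo, key=lambda e: e.position):
            pos = e.position + delta
            if e.type == SUB:
                out.append(EditOperation(scaf, pos, SUB, e.alt, e.ref))
            elif e.type == INS:
                out.append(EditOperation(scaf, pos, DEL, e.alt, ""))
            else:
                out.append(EditOperation(scaf, pos, INS, "", e.ref))
            delta += e.length_delta
    return out


def write_edits_tsv(edits: Iterable[EditOperation], path: str | Path) -> Path:
    """VCF-like TSV of edits (CHROM, POS, TYPE, REF, ALT, DP, AF)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tTYPE\tREF\tALT\tDP\tAF\n")
        for e in edits:
            fh.write(f"{e.scaffold}\t{e.position}\t{e.type}\t"
                     f"{e.ref or '.'}\t{e.alt or '.'}\t{e.depth}\t"
                     f"{e.support:.3f}\n")
    return path
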