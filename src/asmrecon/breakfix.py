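"""Misassembly detection from discordant long-insert end pairs, and
scaffold breaking at supported misjoin points.

Large-insert clone ends (fosmid-scale, ~40 kbp) mapped back to the
assembly should land on one scaffold, in convergent ("innie") orientation,
at a distance consistent with the insert-size model. Clusters of pairs
violating these expectations — with no concordant pair spanning the same
point — mark misjoins; scaffolds are broken there, preferentially at a
gap (scaffolding joins are where the errors live).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import Assembly, GapRecord, Scaffold, ToolConfig, gap_census

CONCORDANT = "CONCORDANT"
WRONG_ORIENTATION = "WRONG_ORIENTATION"
WRONG_SCAFFOLD = "WRONG_SCAFFOLD"
BAD_DISTANCE = "BAD_DISTANCE"
PARTIAL = "PARTIAL"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class EndMapping:
    """One clone end on the assembly; start is the leftmost coordinate."""

    scaffold: str
    start: int
    end: int
    strand: str


@dataclass
class EndPair:
    pair_id: str
    end_a: EndMapping | None
    end_b: EndMapping | None
    unique: bool = True   # False when either end had near-equal alternates


@dataclass
class EndPairObservation:
    pair: EndPair
    verdict: str
    implied_insert: int | None = None

    @property
    def inner_span(self) -> tuple[str, int, int] | None:
        """Interval between the two end alignments (where a misjoin
        separating them must lie)."""
        a, b = self.pair.end_a, self.pair.end_b
        if a is None or b is None or a.scaffold != b.scaffold:
            return None
        left, right = (a, b) if a.start <= b.start else (b, a)
        if right.start <= left.end:
            return None
        return a.scaffold, left.end, right.start

    @property
    def outer_span(self) -> tuple[str, int, int] | None:
        a, b = self.pair.end_a, self.pair.end_b
        if a is None or b is None or a.scaffold != b.scaffold:
            return None
        return a.scaffold, min(a.start, b.start), max(a.end, b.end)


@dataclass
class InsertModel:
    mean: float
    sd: float
    discord_sds: float = 3.0

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.mean - self.discord_sds * self.sd,
                self.mean + self.discord_sds * self.sd)


@dataclass
class BreakCall:
    scaffold: str
    break_start: int
    break_end: int
    supporting_pairs: int
    spanning_concordant: int
    chosen_breakpoint: int
    snapped_to_gap: bool


# ---------------------------------------------------------------------------


def read_end_pairs_tsv(path: str | Path, end_len: int | None = None
                       ) -> list[EndPair]:
    """TSV columns: pairId, scaffoldA, posA, strandA, scaffoldB, posB,
    strandB[, endLen]; '.' marks an unmapped end; pos is the leftmost
    alignment coordinate."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_len = "endLen" in header
        for line in fh:
            f = line.rstrip("\n").split("\t")
            el = int(f[7]) if has_len else (end_len or 500)
            def end(scaf, pos, strand):
                if scaf == "." or pos == ".":
                    return None
                return EndMapping(scaf, int(pos), int(pos) + el, strand)
            pairs.append(EndPair(f[0], end(f[1], f[2], f[3]),
                                 end(f[4], f[5], f[6])))
    return pairs


def implied_insert(a: EndMapping, b: EndMapping) -> int:
    """Outer distance of a same-scaffold pair."""
    return max(a.end, b.end) - min(a.start, b.start)


def is_innie(a: EndMapping, b: EndMapping) -> bool:
    """Convergent orientation: the leftmost end on +, the other on -."""
    left, right = (a, b) if a.start <= b.start else (b, a)
    return left.strand == "+" and right.strand == "-"


def fit_insert_model(pairs: Sequence[EndPair],
                     cfg: ToolConfig | None = None) -> InsertModel:
    """Robust insert-size model from same-scaffold, innie-oriented pairs:
    median and MAD*1.4826 (SD floor 1 bp). Needs >= 50 such pairs."""
    cfg = cfg or ToolConfig()
    inserts = []
    for p in pairs:
        if p.end_a and p.end_b and p.end_a.scaffold == p.end_b.scaffold \
                and is_innie(p.end_a, p.end_b):
            inserts.append(implied_insert(p.end_a, p.end_b))
    if len(inserts) < 50:
        raise ValueError(
            f"only {len(inserts)} candidate pairs; supply an explicit "
            f"InsertModel instead of fitting one")
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    sd = max(1.0, 1.4826 * float(np.median(np.abs(arr - med))))
    return InsertModel(med, sd, cfg.discord_sds)


def classify_pairs(pairs: Iterable[EndPair], model: InsertModel,
                   cfg: ToolConfig | None = None) -> list[EndPairObservation]:
    """One verdict per pair.

    CONCORDANT: both ends unique, one scaffold, innie orientation, implied
    insert within mean +/- discord_sds*sd. Non-unique ends are AMBIGUOUS
    and excluded from break evidence; pairs with a missing end are PARTIAL.
    """
    out = []
    lo, hi = model.bounds
    for p in pairs:
        if p.end_a is None or p.end_b is None:
            out.append(EndPairObservation(p, PARTIAL))
        elif not p.unique:
            out.append(EndPairObservation(p, AMBIGUOUS))
        elif p.end_a.scaffold != p.end_b.scaffold:
            out.append(EndPairObservation(p, WRONG_SCAFFOLD))
        elif not is_innie(p.end_a, p.end_b):
            out.append(EndPairObservation(p, WRONG_ORIENTATION,
                                          implied_insert(p.end_a, p.end_b)))
        else:
            ins = implied_insert(p.end_a, p.end_b)
            verdict = CONCORDANT if lo <= ins <= hi else BAD_DISTANCE
            out.append(EndPairObservation(p, verdict, ins))
    return out


def call_breaks(observations: Sequence[EndPairObservation], asm: Assembly,
                cfg: ToolConfig | None = None) -> list[BreakCall]:
    """Cluster same-scaffold discordant pairs by their inner spans and call
    a break where >= min_discord_cluster spans mutually intersect and some
    point of the intersection has zero concordant spanning coverage.

    The breakpoint snaps to the nearest gap inside the (concordant-free)
    break interval, else to its midpoint. Cross-scaffold pairs alone are
    not evidence.
    """
    cfg = cfg or ToolConfig()
    # pairs are clustered per orientation class: the two junctions of an
    # inversion produce reflected mates in opposite shared-strand classes
    # (++ on one side, -- on the other), so pooling them would cancel out
    discordant: dict[tuple[str, str], list[tuple[int, int]]] = {}
    concordant: dict[str, list[tuple[int, int]]] = {}
    for obs in observations:
        if obs.verdict in (WRONG_ORIENTATION, BAD_DISTANCE):
            span = obs.inner_span
            if span:
                key = (span[0], _orientation_class(obs.pair))
                discordant.setdefault(key, []).append(span[1:])
        elif obs.verdict == CONCORDANT:
            span = obs.outer_span
            if span:
                concordant.setdefault(span[0], []).append(span[1:])
    gaps_by_scaf: dict[str, list[GapRecord]] = {}
    for g in gap_census(asm, cfg.min_gap_len):
        gaps_by_scaf.setdefault(g.scaffold, []).append(g)
    calls: list[BreakCall] = []
    mirror = {"++": "--", "--": "++"}
    for (scaf_name, klass), spans in discordant.items():
        opposite = discordant.get((scaf_name, mirror.get(klass, "")), [])
        spans.sort()
        cluster: list[tuple[int, int]] = []
        ilo = ihi = 0.0
        for span in spans + [(np.inf, np.inf)]:
            if cluster and span[0] < ihi:
                cluster.append(span)
                ilo, ihi = max(ilo, span[0]), min(ihi, span[1])
                continue
            if len(cluster) >= cfg.min_discord_cluster:
                lo, hi = _mirror_refine(klass, float(ilo), float(ihi),
                                        opposite, cfg)
                call = _evaluate_cluster(scaf_name, cluster, (lo, hi),
                                         concordant.get(scaf_name, []),
                                         gaps_by_scaf.get(scaf_name, []))
                if call:
                    calls.append(call)
            if not np.isinf(span[0]):
                cluster = [span]
                ilo, ihi = span
    calls.sort(key=lambda c: (c.scaffold, c.chosen_breakpoint))
    return calls


def _mirror_refine(klass: str, ilo: float, ihi: float,
                   opposite: list[tuple[int, int]],
                   cfg: ToolConfig) -> tuple[float, float]:
    """Tighten an inversion cluster's break interval with the mirror
    cluster's near ends.

    At an inverted segment's left junction the ++ pairs approach from the
    left (their inner starts bound the junction from below) while the --
    pairs of the *right* junction have their left ends just inside the
    segment — bounding the same left junction from above. Symmetrically
    for the right junction.
    """
    reach = cfg.insert_mean + cfg.discord_sds * cfg.insert_sd
    if klass == "++":
        ubs = [s for s, _ in opposite if ilo < s <= ilo + 2 * reach]
        if ubs:
            ihi = min(ihi, min(ubs))
    elif klass == "--":
        lbs = [e for _, e in opposite if ihi - 2 * reach <= e < ihi]
        if lbs:
            ilo = max(ilo, max(lbs))
    return ilo, ihi


def _orientation_class(pair: EndPair) -> str:
    """Strands of the two ends in left-to-right position order."""
    a, b = pair.end_a, pair.end_b
    left, right = (a, b) if a.start <= b.start else (b, a)
    return left.strand + right.strand


def _evaluate_cluster(scaffold: str, cluster: list[tuple[int, int]],
                      interval: tuple[int, int],
                      concordant: list[tuple[int, int]],
                      gaps: list[GapRecord]) -> BreakCall | None:
    ilo, ihi = int(interval[0]), int(interval[1])
    if ihi <= ilo:
        return None
    # concordant physical coverage over the intersection interval
    events = []
    for s, e in concordant:
        if e > ilo and s < ihi:
            events.append((max(s, ilo), 1))
            events.append((min(e, ihi), -1))
    events.sort()
    cov = 0
    min_cov = 0 if not events else np.inf
    free_lo, free_hi = (ilo, ihi) if not events else (None, None)
    pos = ilo
    for at, delta in events + [(ihi, 0)]:
        if at > pos and cov < min_cov:
            min_cov, free_lo, free_hi = cov, pos, at
        cov += delta
        pos = at
    if not events:
        min_cov = 0
    if min_cov > 0:
        return None
    # snap to the nearest gap inside the concordant-free window
    mid = (free_lo + free_hi) // 2
    best_gap = None
    for g in gaps:
        if free_lo <= g.start and g.end <= free_hi:
            gmid = (g.start + g.end) // 2
            if best_gap is None or abs(gmid - mid) < abs(best_gap - mid):
                best_gap = gmid
    return BreakCall(scaffold, ilo, ihi, len(cluster), int(min_cov),
                     best_gap if best_gap is not None else mid,
                     best_gap is not None)


def apply_breaks(asm: Assembly, calls: Sequence[BreakCall],
                 cfg: ToolConfig | None = None) -> Assembly:
    """Split scaffolds at the chosen breakpoints.

    A breakpoint inside a gap removes the gap's Ns entirely; otherwise the
    split is between bases and no sequence is lost. Pieces are renamed
    <scaffold>_1, _2, ... Non-N bases are conserved exactly.
    """
    cfg = cfg or ToolConfig()
    by_scaf: dict[str, list[int]] = {}
    for c in calls:
        by_scaf.setdefault(c.scaffold, []).append(c.chosen_breakpoint)
    new_scaffolds: list[Scaffold] = []
    for scaf in asm:
        points = sorted(by_scaf.get(scaf.name, []))
        if not points:
            new_scaffolds.append(Scaffold(scaf.name, scaf.sequence))
            continue
        gaps = scaf.gaps(cfg.min_gap_len)
        cuts: list[tuple[int, int]] = []  # half-open removed interval
        for p in points:
            hit = next((g for g in gaps if g.start <= p < g.end), None)
            cuts.append((hit.start, hit.end) if hit else (p, p))
        pieces = []
        pos = 0
        for s, e in sorted(set(cuts)):
            if s > pos:
                pieces.append(scaf.sequence[pos:s])
            pos = max(pos, e)
        if pos < len(scaf):
            pieces.append(scaf.sequence[pos:])
        pieces = [p for p in pieces if p]
        if len(pieces) == 1:
            new_scaffolds.append(Scaffold(scaf.name, pieces[0]))
        else:
            for i, p in enumerate(pieces, start=1):
                new_scaffolds.append(Scaffold(f"{scaf.name}_{i}", p))
    return Assembly(asm.name, new_scaffolds)


def write_breaks_bed(calls: Iterable[BreakCall], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.scaffold}\t{c.break_start}\t{c.break_end}\t"
                     f"break;support={c.supporting_pairs};"
                     f"bp={c.chosen_breakpoint};gap={int(c.snapped_to_gap)}\n")
    return path
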