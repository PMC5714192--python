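"""Segmental-duplication detection by two complementary routes.

WGAC (whole-genome assembly comparison): align the repeat-masked assembly
to itself and keep duplicated blocks of at least 1 kbp at 90% identity or
higher, reported both as redundant pairwise alignments and as the
non-redundant base-level union.

WSSD (whole-genome shotgun sequence detection): place reads at over 94%
identity, measure windowed read depth, calibrate against known unique
regions, and call runs of significantly elevated windows at least 10 kbp
long. WSSD sees duplications the assembly collapsed (only one copy
assembled), which WGAC by construction cannot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .align import edlib_stats, encode, kmer_codes
from .core import (Assembly, BedInterval, ToolConfig, intersect_bp,
                   merge_intervals, subtract_intervals, union_bp)


@dataclass
class DuplicationCall:
    scaffold: str
    start: int
    end: int
    method: str                  # WGAC or WSSD
    identity: float              # pairwise identity (WGAC) or depth ratio
    mate: tuple[str, int, int] | None = None  # partner interval, WGAC only
    mate_strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# WGAC


def wgac_self_compare(asm: Assembly, repeat_mask: Sequence[BedInterval] = (),
                      cfg: ToolConfig | None = None
                      ) -> tuple[list[DuplicationCall], dict[str, list[tuple[int, int]]]]:
    """Self-comparison of the repeat-masked assembly.

    Pipeline: hard-mask annotated repeats; collect k-mers shared between
    two loci (both orientations); cluster shared k-mers by diagonal; align
    each clustered locus pair (edlib, exact match counts); chain collinear
    hits; keep chains >= wgac_min_len at >= wgac_min_ident, dropping the
    trivial self-diagonal. Returns the redundant pair list (each pair and
    its mirror) plus the non-redundant interval union per scaffold.
    """
    cfg = cfg or ToolConfig()
    k = cfg.kmer_size
    # concatenate masked scaffolds with sentinels
    parts, offsets, names = [], [], []
    pos = 0
    for scaf in asm:
        arr = encode(scaf.sequence)
        for iv in repeat_mask:
            if iv.chrom == scaf.name:
                arr[iv.start:iv.end] = 255
        offsets.append(pos)
        names.append(scaf.name)
        parts.append(arr)
        pos += len(arr)
        parts.append(np.full(1, 255, dtype=np.uint8))
        pos += 1
    cat = np.concatenate(parts)
    seqs = {s.name: s.sequence for s in asm}
    offsets = np.array(offsets, dtype=np.int64)

    pairs = _seed_pairs(cat, k, cfg)
    raw_hits: list[DuplicationCall] = []
    for strand, plist in pairs.items():
        for qlo, qhi, tlo, thi, n_seeds in plist:
            hit = _align_locus_pair(cat, seqs, offsets, names, qlo, qhi,
                                    tlo, thi, strand, k)
            if hit is not None:
                raw_hits.append(hit)
    chained = _chain_hits(raw_hits, cfg)
    calls = [h for h in chained
             if h.length >= cfg.wgac_min_len
             and (h.mate[2] - h.mate[1]) >= cfg.wgac_min_len
             and h.identity >= cfg.wgac_min_ident]
    # mirror each pair
    mirrored: list[DuplicationCall] = []
    for c in calls:
        mirrored.append(c)
        mirrored.append(DuplicationCall(
            c.mate[0], c.mate[1], c.mate[2], "WGAC", c.identity,
            (c.scaffold, c.start, c.end), c.mate_strand))
    nr: dict[str, list[tuple[int, int]]] = {}
    for c in mirrored:
        nr.setdefault(c.scaffold, []).append((c.start, c.end))
    nr = {s: merge_intervals(v) for s, v in nr.items()}
    return mirrored, nr


def _seed_pairs(cat: np.ndarray, k: int, cfg: ToolConfig,
                max_occ: int = 50, diag_band: int = 100,
                chain_gap: int = 2000, min_seeds: int = 3) -> dict:
    """Diagonal-clustered k-mer sharing within the masked concatenation.

    '+': both loci forward; '-': second locus on the reverse strand.
    Returns clusters as (qlo, qhi, tlo, thi, n_seeds) in concat coords.
    """
    codes, positions = kmer_codes(cat, k)
    order = np.argsort(codes, kind="stable")
    sc, sp = codes[order], positions[order]
    boundaries = np.flatnonzero(np.diff(sc) != 0) + 1
    groups = np.split(sp, boundaries)
    fwd_a, fwd_b = [], []
    for grp in groups:
        n = len(grp)
        if n < 2 or n > max_occ:
            continue
        g = np.sort(grp)
        ia, ib = np.triu_indices(n, k=1)
        fwd_a.append(g[ia])
        fwd_b.append(g[ib])
    out = {}
    if fwd_a:
        a = np.concatenate(fwd_a)
        b = np.concatenate(fwd_b)
        keep = b - a >= k  # drop the trivial self-diagonal / overlaps
        out["+"] = _cluster(a[keep], b[keep], k, diag_band, chain_gap,
                            min_seeds)
    else:
        out["+"] = []
    # reverse strand: match forward k-mers against reverse-complement codes
    rc = _revcomp_codes(codes, k)
    rc_order = np.argsort(rc, kind="stable")
    src, srp = rc[rc_order], positions[rc_order]
    lo = np.searchsorted(src, sc, side="left")
    hi = np.searchsorted(src, sc, side="right")
    counts = hi - lo
    sel = np.flatnonzero((counts > 0) & (counts <= max_occ))
    rev_a, rev_b = [], []
    for i in sel:
        p1 = sp[i]
        for p2 in srp[lo[i]:hi[i]]:
            if p1 + k <= p2:  # each pair once, non-overlapping
                rev_a.append(p1)
                rev_b.append(p2)
    if rev_a:
        a = np.asarray(rev_a, dtype=np.int64)
        b = np.asarray(rev_b, dtype=np.int64)
        # on the reverse strand collinear hits share an antidiagonal
        out["-"] = _cluster(a, b, k, diag_band, chain_gap, min_seeds,
                            antidiagonal=True)
    else:
        out["-"] = []
    return out


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of each k-mer code (2-bit encoding)."""
    comp = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        comp = comp * 4 + (3 - (c % 4))
        c //= 4
    return comp


def _cluster(a: np.ndarray, b: np.ndarray, k: int, diag_band: int,
             chain_gap: int, min_seeds: int,
             antidiagonal: bool = False) -> list[tuple[int, int, int, int, int]]:
    if len(a) == 0:
        return []
    diag = (a + b) if antidiagonal else (b - a)
    order = np.lexsort((a, diag))
    diag, a, b = diag[order], a[order], b[order]
    clusters = []
    start = 0
    for i in range(1, len(diag) + 1):
        if (i == len(diag) or diag[i] - diag[i - 1] > diag_band
                or abs(int(a[i]) - int(a[i - 1])) > chain_gap):
            qa, qb = a[start:i], b[start:i]
            if len(qa) >= min_seeds:
                clusters.append((int(qa.min()), int(qa.max()) + k,
                                 int(qb.min()), int(qb.max()) + k, len(qa)))
            start = i
    return clusters


def _align_locus_pair(cat: np.ndarray, seqs: dict[str, str],
                      offsets: np.ndarray, names: list[str],
                      qlo: int, qhi: int, tlo: int, thi: int,
                      strand: str, k: int) -> DuplicationCall | None:
    from .core import revcomp

    def locate(lo, hi):
        i = int(np.searchsorted(offsets, lo, side="right")) - 1
        name = names[i]
        return name, int(lo - offsets[i]), int(hi - offsets[i])

    qn, qs, qe = locate(qlo, qhi)
    tn, ts, te = locate(tlo, thi)
    if qe > len(seqs[qn]) or te > len(seqs[tn]):
        return None  # cluster crossed a scaffold sentinel
    if qn == tn and max(qs, ts) < min(qe, te):
        return None  # self-overlapping locus pair (trivial diagonal)
    qseq = seqs[qn][qs:qe]
    tseq = seqs[tn][ts:te]
    if strand == "-":
        tseq = revcomp(tseq)
    res = edlib.align(qseq, tseq, mode="NW", task="path")
    if res["editDistance"] < 0:
        return None
    matches, cols = edlib_stats(res["cigar"])
    return DuplicationCall(qn, qs, qe, "WGAC", matches / cols,
                           (tn, ts, te), strand)


def _chain_hits(hits: list[DuplicationCall], cfg: ToolConfig,
                chain_gap: int = 2000) -> list[DuplicationCall]:
    """Merge collinear hits of the same locus pair separated by <= the
    chain gap (e.g. interrupted by a masked repeat); the chain identity is
    the column-weighted mean of its members."""
    hits = sorted(hits, key=lambda h: (h.scaffold, h.mate[0], h.mate_strand,
                                       h.start))
    out: list[DuplicationCall] = []
    for h in hits:
        # carry matches/columns through the weighted-identity merge
        h_cols = h.length
        h_matches = h.identity * h_cols
        prev = out[-1] if out else None
        if (prev is not None and prev.scaffold == h.scaffold
                and prev.mate[0] == h.mate[0]
                and prev.mate_strand == h.mate_strand
                and 0 <= h.start - prev.end <= chain_gap
                and ((h.mate_strand == "+"
                      and 0 <= h.mate[1] - prev.mate[2] <= chain_gap)
                     or (h.mate_strand == "-"
                         and 0 <= prev.mate[1] - h.mate[2] <= chain_gap))):
            p_cols = prev.length
            p_matches = prev.identity * p_cols
            mate = (prev.mate[0],
                    min(prev.mate[1], h.mate[1]),
                    max(prev.mate[2], h.mate[2]))
            out[-1] = DuplicationCall(
                prev.scaffold, prev.start, h.end, "WGAC",
                (p_matches + h_matches) / (p_cols + h_cols),
                mate, prev.mate_strand)
        else:
            out.append(h)
    return out


def nonredundant_bp(nr: dict[str, list[tuple[int, int]]], asm: Assembly,
                    scope: Iterable[str] | None = None,
                    cfg: ToolConfig | None = None) -> tuple[int, float]:
    """Non-redundant duplicated bp and its fraction of non-gap bases.

    ``scope`` restricts both numerator and denominator to the named
    scaffolds (e.g. placed chromosomes); default is genome-wide.
    """
    cfg = cfg or ToolConfig()
    names = set(scope) if scope is not None else {s.name for s in asm}
    bp = sum(union_bp(v) for s, v in nr.items() if s in names)
    denom = 0
    for scaf in asm:
        if scaf.name in names:
            denom += len(scaf) - sum(g.length for g in
                                     scaf.gaps(cfg.min_gap_len))
    return bp, (bp / denom if denom else 0.0)


# ---------------------------------------------------------------------------
# WSSD


@dataclass
class DepthProfile:
    scaffolds: list[str]
    window_scaffold: np.ndarray   # index into scaffolds
    window_start: np.ndarray
    window_end: np.ndarray
    raw_depth: np.ndarray
    corrected_depth: np.ndarray
    unique_mean: float
    unique_sd: float
    window_len: int
    step: int
    # step-resolution tiles used only to refine call boundaries
    fine_scaffold: np.ndarray | None = None
    fine_start: np.ndarray | None = None
    fine_depth: np.ndarray | None = None
    fine_mean: float = 0.0
    fine_sd: float = 0.0


def wssd_depth(placements: Sequence, asm: Assembly,
               unique_regions: Sequence[BedInterval],
               cfg: ToolConfig | None = None) -> DepthProfile:
    """Windowed read depth calibrated on known unique regions.

    Only placements with identity strictly above ``wssd_read_ident`` count
    toward depth (the classic "over 94% identity" read filter). Windows
    overlapping gaps are excluded; calibration statistics come only from
    windows fully inside ``unique_regions``. Raises if fewer than 100
    calibration windows exist.
    """
    cfg = cfg or ToolConfig()
    win, step = cfg.wssd_window, cfg.wssd_step
    cov: dict[str, np.ndarray] = {}
    for scaf in asm:
        cov[scaf.name] = np.zeros(len(scaf) + 1, dtype=np.int32)
    for p in placements:
        if p.identity > cfg.wssd_read_ident:
            cov[p.scaffold][p.start] += 1
            cov[p.scaffold][p.end] -= 1
    uniq: dict[str, list[tuple[int, int]]] = {}
    for iv in unique_regions:
        uniq.setdefault(iv.chrom, []).append((iv.start, iv.end))
    uniq = {c: merge_intervals(v) for c, v in uniq.items()}

    scaffolds, wsc, wst, wen, dep, in_uniq = [], [], [], [], [], []
    fsc, fst, fdep, f_uniq = [], [], [], []
    for si, scaf in enumerate(asm):
        depth = np.cumsum(cov[scaf.name][:-1])
        gaps = [(g.start, g.end) for g in scaf.gaps(cfg.min_gap_len)]
        scaffolds.append(scaf.name)
        cum = np.concatenate(([0], np.cumsum(depth, dtype=np.int64)))
        useg = uniq.get(scaf.name, [])
        for s in range(0, max(1, len(scaf) - win + 1), step):
            e = s + win
            if e > len(scaf):
                break
            if any(gs < e and ge > s for gs, ge in gaps):
                continue
            wsc.append(si)
            wst.append(s)
            wen.append(e)
            dep.append((cum[e] - cum[s]) / win)
            in_uniq.append(any(us <= s and e <= ue for us, ue in useg))
        for s in range(0, max(1, len(scaf) - step + 1), step):
            e = s + step
            if e > len(scaf):
                break
            if any(gs < e and ge > s for gs, ge in gaps):
                continue
            fsc.append(si)
            fst.append(s)
            fdep.append((cum[e] - cum[s]) / step)
            f_uniq.append(any(us <= s and e <= ue for us, ue in useg))
    wsc = np.array(wsc); wst = np.array(wst); wen = np.array(wen)
    dep = np.array(dep); in_uniq = np.array(in_uniq, dtype=bool)
    fsc = np.array(fsc); fst = np.array(fst)
    fdep = np.array(fdep); f_uniq = np.array(f_uniq, dtype=bool)
    if int(in_uniq.sum()) < 100:
        raise ValueError(f"only {int(in_uniq.sum())} calibration windows in "
                         f"unique regions; need >= 100")
    mean = float(dep[in_uniq].mean())
    sd = float(dep[in_uniq].std(ddof=1))
    return DepthProfile(scaffolds, wsc, wst, wen, dep, dep.copy(),
                        mean, max(sd, 1e-9), win, step,
                        fsc, fst, fdep,
                        float(fdep[f_uniq].mean()),
                        max(float(fdep[f_uniq].std(ddof=1)), 1e-9))


def wssd_call(profile: DepthProfile,
              cfg: ToolConfig | None = None) -> list[DuplicationCall]:
    """Merge runs of depth-elevated windows into duplication calls.

    A window is flagged when corrected depth exceeds
    unique_mean + wssd_depth_sds * unique_sd; runs of flagged windows
    (tolerating <= wssd_merge_slop unflagged windows inside) at least
    wssd_min_len long become calls, with depth ratio relative to the
    unique mean as the evidence value.
    """
    cfg = cfg or ToolConfig()
    thr = profile.unique_mean + cfg.wssd_depth_sds * profile.unique_sd
    calls: list[DuplicationCall] = []
    for si, name in enumerate(profile.scaffolds):
        sel = profile.window_scaffold == si
        starts = profile.window_start[sel]
        ends = profile.window_end[sel]
        depth = profile.corrected_depth[sel]
        flagged = depth > thr
        idx = np.flatnonzero(flagged)
        if len(idx) == 0:
            continue
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            if i - runs[-1][-1] <= cfg.wssd_merge_slop + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            s, e = int(starts[run[0]]), int(ends[run[-1]])
            s, e = _refine_edges(profile, cfg, si, s, e)
            if e - s >= cfg.wssd_min_len:
                ratio = float(np.mean(depth[run]) / profile.unique_mean)
                calls.append(DuplicationCall(name, s, e, "WSSD", ratio))
    return calls


def _refine_edges(profile: DepthProfile, cfg: ToolConfig, si: int,
                  s: int, e: int) -> tuple[int, int]:
    """Trim a merged run to the outermost step-resolution tiles that are
    themselves depth-elevated — full-window flagging overhangs true edges
    by up to a window length, which step tiles recover."""
    if profile.fine_start is None:
        return s, e
    thr = profile.fine_mean + cfg.wssd_depth_sds * profile.fine_sd
    sel = (profile.fine_scaffold == si) & (profile.fine_start >= s) \
        & (profile.fine_start + profile.step <= e)
    starts = profile.fine_start[sel]
    hot = profile.fine_depth[sel] > thr
    idx = np.flatnonzero(hot)
    if len(idx) == 0:
        return s, e
    return int(starts[idx[0]]), int(starts[idx[-1]] + profile.step)


def default_unique_regions(asm: Assembly,
                           wgac_nr: dict[str, list[tuple[int, int]]],
                           cfg: ToolConfig | None = None
                           ) -> list[BedInterval]:
    """Operational "known unique regions": the WGAC-negative, gap-free
    fraction of the assembly."""
    cfg = cfg or ToolConfig()
    out = []
    for scaf in asm:
        whole = [(0, len(scaf))]
        gaps = [(g.start, g.end) for g in scaf.gaps(cfg.min_gap_len)]
        rest = subtract_intervals(whole, gaps + wgac_nr.get(scaf.name, []))
        out.extend(BedInterval(scaf.name, s, e) for s, e in rest)
    return out


def compare_wgac_wssd(wgac_nr: dict[str, list[tuple[int, int]]],
                      wssd_calls: Sequence[DuplicationCall],
                      scope: Iterable[str] | None = None) -> dict[str, int]:
    """Base-pair concordance between the two call sets: bp detected by
    both, by WGAC only, and by WSSD only."""
    wssd: dict[str, list[tuple[int, int]]] = {}
    for c in wssd_calls:
        wssd.setdefault(c.scaffold, []).append((c.start, c.end))
    wssd = {s: merge_intervals(v) for s, v in wssd.items()}
    names = set(wgac_nr) | set(wssd)
    if scope is not None:
        names &= set(scope)
    both = wgac_only = wssd_only = 0
    for name in names:
        a = wgac_nr.get(name, [])
        b = wssd.get(name, [])
        inter = intersect_bp(a, b)
        both += inter
        wgac_only += union_bp(a) - inter
        wssd_only += union_bp(b) - inter
    return {"both_bp": both, "wgac_only_bp": wgac_only,
            "wssd_only_bp": wssd_only}


def wgac_calls_at(calls: Sequence[DuplicationCall], min_len: int,
                  min_ident: float) -> dict[str, list[tuple[int, int]]]:
    """Non-redundant WGAC intervals restricted to stricter thresholds
    (e.g. >= 10 kbp at >= 94% for the WSSD comparison)."""
    nr: dict[str, list[tuple[int, int]]] = {}
    for c in calls:
        if c.length >= min_len and c.identity >= min_ident:
            nr.setdefault(c.scaffold, []).append((c.start, c.end))
    return {s: merge_intervals(v) for s, v in nr.items()}
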