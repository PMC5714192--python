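"""Assembly contiguity statistics, annotation deltas, alignment identity
summaries, and the feature permutation enrichment test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (AlignmentRecord, Assembly, BedInterval, ToolConfig,
                   gap_census, merge_intervals, union_bp)


def nxx(lengths: Sequence[int], x: float = 0.5) -> int:
    """Nxx statistic: the smallest length L among the inputs such that
    pieces of length >= L together contain at least x of the total bases.

    When the cumulative sum hits exactly x*total, that piece's length is
    returned (>= convention), so results are bit-stable.
    """
    if not 0 < x <= 1:
        raise ValueError("x must be in (0, 1]")
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("nxx of an empty length list")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, x * cum[-1], side="left"))
    return int(arr[idx])


@dataclass
class AssemblyStats:
    scaffold_n50: int
    contig_n50: int
    contig_n90: int
    total_len: int
    total_len_no_n: int
    n_scaffolds: int
    n_contigs: int
    n_gaps: int
    per_scaffold: pd.DataFrame | None = None

    #: row labels used by the TSV report, mirroring the classic
    #: assembly-comparison table layout
    ROW_NAMES = ("Scaffold N50, bp", "Contig N50, bp", "Contig N90, bp",
                 "Assembly length, bp", "Assembly length w/o Ns, bp",
                 "Scaffolds", "Contigs", "Gaps")

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.scaffold_n50, self.contig_n50, self.contig_n90,
             self.total_len, self.total_len_no_n, self.n_scaffolds,
             self.n_contigs, self.n_gaps],
            index=list(self.ROW_NAMES), dtype="int64")


def assembly_stats(asm: Assembly, cfg: ToolConfig | None = None,
                   per_scaffold: bool = False) -> AssemblyStats:
    """Contiguity statistics under the >= min_gap_len N-run gap definition.

    "length w/o Ns" counts every non-N base: N-runs too short to qualify
    as gaps are still Ns and therefore excluded from it, while remaining
    contig-internal for the contig statistics.
    """
    cfg = cfg or ToolConfig()
    scaffold_lens = [len(s) for s in asm.scaffolds]
    contig_lens: list[int] = []
    n_gaps = 0
    no_n = 0
    rows = []
    for scaf in asm:
        gaps = scaf.gaps(cfg.min_gap_len)
        contigs = scaf.contigs(cfg.min_gap_len)
        clens = [e - s for s, e in contigs]
        contig_lens.extend(clens)
        n_gaps += len(gaps)
        no_n += len(scaf) - scaf.sequence.count("N")
        if per_scaffold:
            rows.append({"scaffold": scaf.name, "length": len(scaf),
                         "contigs": len(contigs), "gaps": len(gaps),
                         "contig_n50": nxx(clens) if clens else 0})
    return AssemblyStats(
        scaffold_n50=nxx(scaffold_lens),
        contig_n50=nxx(contig_lens) if contig_lens else 0,
        contig_n90=nxx(contig_lens, 0.9) if contig_lens else 0,
        total_len=sum(scaffold_lens),
        total_len_no_n=no_n,
        n_scaffolds=len(scaffold_lens),
        n_contigs=len(contig_lens),
        n_gaps=n_gaps,
        per_scaffold=pd.DataFrame(rows) if per_scaffold else None)


# ---------------------------------------------------------------------------
# annotation deltas


def annotation_delta(old: Iterable[BedInterval],
                     new: Iterable[BedInterval]) -> pd.DataFrame:
    """Per-family non-redundant covered bp in each annotation set, with
    absolute and percent increase; families are the BED name column.

    Overlapping intervals within a family are unioned (counted once). A
    family present in only one set gets a zero baseline on the other side.
    The returned frame carries the median percent increase across families
    in ``df.attrs['median_pct_increase']``.
    """
    def family_bp(ivs: Iterable[BedInterval]) -> dict[str, int]:
        grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for iv in ivs:
            grouped.setdefault((iv.name, iv.chrom), []).append(
                (iv.start, iv.end))
        out: dict[str, int] = {}
        for (fam, _), pairs in grouped.items():
            out[fam] = out.get(fam, 0) + union_bp(pairs)
        return out

    old_bp = family_bp(old)
    new_bp = family_bp(new)
    fams = sorted(set(old_bp) | set(new_bp))
    rows = []
    for fam in fams:
        o = old_bp.get(fam, 0)
        n = new_bp.get(fam, 0)
        rows.append({"family": fam, "old_bp": o, "new_bp": n,
                     "delta_bp": n - o,
                     "pct_increase": (100.0 * (n - o) / o) if o else np.nan})
    df = pd.DataFrame(rows).set_index("family")
    finite = df["pct_increase"].dropna()
    df.attrs["median_pct_increase"] = (float(finite.median())
                                       if len(finite) else float("nan"))
    return df


def identity_summary(alns: Sequence[AlignmentRecord],
                     weighting: str = "column-weighted") -> float:
    """Mean alignment identity across records.

    'column-weighted' (default): sum(matches)/sum(aligned_columns), the
    per-column average; 'record-mean': unweighted mean of per-record
    identities.
    """
    if not alns:
        raise ValueError("identity_summary of an empty alignment list")
    if weighting == "column-weighted":
        return sum(a.matches for a in alns) / sum(a.aligned_columns
                                                  for a in alns)
    if weighting == "record-mean":
        return float(np.mean([a.identity for a in alns]))
    raise ValueError(f"unknown weighting {weighting!r}")


# ---------------------------------------------------------------------------
# feature permutation test


@dataclass
class EnrichmentResult:
    observed_overlap_fraction: float
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    empirical_p: float
    reps: int
    seed: int


def permutation_enrichment(query: Sequence[BedInterval],
                           features: Sequence[BedInterval],
                           universe: Sequence[BedInterval],
                           cfg: ToolConfig | None = None,
                           statistic: str = "fraction-intersecting"
                           ) -> EnrichmentResult:
    """Empirical enrichment of query intervals in features.

    Observed statistic (default): the fraction of query intervals with at
    least 1 bp of feature overlap. The null re-places each query interval
    uniformly at random (length-preserving, same scaffold) within the
    universe — the non-gap placement space — ``cfg.perm_reps`` times. The
    one-sided empirical P uses the +1 correction:
    P = (1 + #{null >= observed}) / (reps + 1), so the smallest reachable
    P is 1/(reps+1).

    'bp-overlap' uses the total overlapping bp fraction instead of the
    interval-count fraction (non-default variant).
    """
    cfg = cfg or ToolConfig()
    if not query:
        raise ValueError("empty query set")
    rng = np.random.default_rng(cfg.rng_seed)
    reps = cfg.perm_reps

    # per-scaffold universe segments and merged features
    segs: dict[str, list[tuple[int, int]]] = {}
    for iv in universe:
        segs.setdefault(iv.chrom, []).append((iv.start, iv.end))
    segs = {c: merge_intervals(v) for c, v in segs.items()}
    feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[tuple[int, int]]] = {}
    for iv in features:
        grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for c, v in grouped.items():
        merged = merge_intervals(v)
        feats[c] = (np.array([s for s, _ in merged], dtype=np.int64),
                    np.array([e for _, e in merged], dtype=np.int64))

    def overlap_bp(chrom: str, starts: np.ndarray, length: int) -> np.ndarray:
        """bp of feature overlap for intervals [starts, starts+length)."""
        if chrom not in feats:
            return np.zeros(len(starts), dtype=np.int64)
        fs, fe = feats[chrom]
        ends = starts + length
        lo = np.searchsorted(fe, starts, side="right")
        hi = np.searchsorted(fs, ends, side="left")
        out = np.zeros(len(starts), dtype=np.int64)
        # most intervals overlap few features; loop the distinct cases
        multi = hi > lo
        for i in np.flatnonzero(multi):
            s, e = starts[i], ends[i]
            out[i] = np.sum(np.minimum(fe[lo[i]:hi[i]], e)
                            - np.maximum(fs[lo[i]:hi[i]], s))
        return out

    weighted = statistic == "bp-overlap"
    total_q_bp = sum(iv.length for iv in query)

    obs_raw = 0.0
    null_raw = np.zeros(reps, dtype=np.float64)
    for iv in query:
        if iv.chrom not in segs:
            raise ValueError(f"query scaffold {iv.chrom} absent from universe")
        ob = overlap_bp(iv.chrom, np.array([iv.start]), iv.length)[0]
        obs_raw += ob if weighted else (ob > 0)
        cand = [(s, e) for s, e in segs[iv.chrom] if e - s >= iv.length]
        if not cand:
            raise ValueError(f"query interval of {iv.length} bp is longer "
                             f"than every universe segment on {iv.chrom}")
        w = np.array([e - s - iv.length + 1 for s, e in cand], dtype=float)
        seg_idx = rng.choice(len(cand), size=reps, p=w / w.sum())
        seg_starts = np.array([s for s, _ in cand], dtype=np.int64)[seg_idx]
        offs = np.floor(rng.random(reps) * w[seg_idx]).astype(np.int64)
        starts = seg_starts + offs
        nb = overlap_bp(iv.chrom, starts, iv.length)
        null_raw += nb if weighted else (nb > 0)

    denom = total_q_bp if weighted else len(query)
    observed = obs_raw / denom
    null = null_raw / denom
    p = (1 + int(np.sum(null >= observed))) / (reps + 1)
    qs = np.quantile(null, [0.05, 0.5, 0.95])
    return EnrichmentResult(
        observed_overlap_fraction=float(observed),
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)) if reps > 1 else 0.0,
        null_quantiles={"q05": float(qs[0]), "q50": float(qs[1]),
                        "q95": float(qs[2])},
        empirical_p=float(p), reps=reps, seed=cfg.rng_seed)


def non_gap_universe(asm: Assembly, cfg: ToolConfig | None = None
                     ) -> list[BedInterval]:
    """Contig intervals of the assembly — the gap-excluded placement space
    the permutation null draws from."""
    cfg = cfg or ToolConfig()
    out = []
    for scaf in asm:
        for s, e in scaf.contigs(cfg.min_gap_len):
            out.append(BedInterval(scaf.name, s, e))
    return out
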