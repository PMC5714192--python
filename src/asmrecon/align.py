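"""Desk-scale seeded aligner: exact k-mer seeding + edlib gapped extension.

Intended for mapping kbp-scale queries (gap flanks, clone ends) onto Mbp-scale
targets, and for assembly self-comparison. Not a general-purpose read mapper:
inputs beyond ~10 Mbp should be aligned externally and imported as PAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .core import AlignmentRecord, Assembly, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (incl. N) -> 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of every valid (ACGT-only) k-mer in ``arr``."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = arr[j:j + n]
        codes = codes * 4 + window
        valid &= window != 255
    pos = np.flatnonzero(valid)
    return codes[pos], pos


def edlib_stats(cigar: str) -> tuple[int, int]:
    """(matches, aligned_columns) from an edlib extended CIGAR (=/X/I/D)."""
    import re
    matches = cols = 0
    for n, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(n)
        cols += n
        if op == "=":
            matches += n
    return matches, cols


@dataclass
class _Hit:
    tstart: int
    tend: int
    n_seeds: int


class KmerIndex:
    """Sorted-array k-mer index over all scaffolds of a target assembly."""

    def __init__(self, target: Assembly, k: int = 15):
        self.target = target
        self.k = k
        # concatenate scaffolds with a 255 sentinel so no k-mer spans two
        parts, offsets, names = [], [], []
        pos = 0
        for scaf in target:
            offsets.append(pos)
            names.append(scaf.name)
            parts.append(encode(scaf.sequence))
            pos += len(scaf.sequence)
            parts.append(np.full(1, 255, dtype=np.uint8))
            pos += 1
        self.offsets = np.array(offsets, dtype=np.int64)
        self.names = names
        self.lengths = [len(s.sequence) for s in target]
        cat = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        codes, positions = kmer_codes(cat, k)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = positions[order]

    def scaffold_of(self, concat_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, concat_pos, side="right")) - 1
        return self.names[i], int(concat_pos - self.offsets[i])

    def lookup(self, codes: np.ndarray, max_occ: int = 100
               ) -> tuple[np.ndarray, np.ndarray]:
        """(query_idx, target_concat_pos) seed matches, skipping k-mers with
        more than ``max_occ`` target occurrences."""
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= max_occ)
        qi_list, tp_list = [], []
        for qi in np.flatnonzero(keep):
            tp = self.sorted_pos[lo[qi]:hi[qi]]
            qi_list.append(np.full(len(tp), qi, dtype=np.int64))
            tp_list.append(tp)
        if not qi_list:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        return np.concatenate(qi_list), np.concatenate(tp_list)


def _cluster_diagonals(qpos: np.ndarray, tpos: np.ndarray, k: int,
                       diag_band: int = 100, chain_gap: int = 2000,
                       min_seeds: int = 2) -> list[tuple[int, int, int, int, int]]:
    """Group seed matches into candidate loci.

    Returns (qlo, qhi, tlo, thi, n_seeds) per cluster, with hi exclusive.
    """
    if len(qpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    diag, qpos, tpos = diag[order], qpos[order], tpos[order]
    clusters = []
    start = 0
    for i in range(1, len(diag) + 1):
        # seeds sorted by (diagonal, target pos): break a cluster on a
        # diagonal jump or a target-position jump beyond the chain gap
        if (i == len(diag)
                or diag[i] - diag[i - 1] > diag_band
                or abs(int(tpos[i]) - int(tpos[i - 1])) > chain_gap):
            q = qpos[start:i]
            t = tpos[start:i]
            if len(q) >= min_seeds:
                clusters.append((int(q.min()), int(q.max()) + k,
                                 int(t.min()), int(t.max()) + k, len(q)))
            start = i
    return clusters


def map_query(index: KmerIndex, query: str, query_name: str = "query",
              max_occ: int = 100, min_seeds: int = 2, max_hits: int = 20,
              pad: int = 64) -> list[AlignmentRecord]:
    """Map one query against the index, both strands, best hits first.

    Each candidate seed cluster is refined with an infix (glocal) edlib
    alignment of the full query into the padded target window, yielding
    exact match counts from the extended CIGAR. Score = matches − 4·errors.
    """
    qlen = len(query)
    records: list[AlignmentRecord] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        codes, qpos = kmer_codes(encode(qseq), index.k)
        qi, tp = index.lookup(codes, max_occ=max_occ)
        if len(qi) == 0:
            continue
        clusters = _cluster_diagonals(qpos[qi], tp, index.k,
                                      min_seeds=min_seeds)
        clusters.sort(key=lambda c: -c[4])
        for qlo, qhi, tlo, thi, n_seeds in clusters[:max_hits]:
            scaf_name, local_lo = index.scaffold_of(tlo)
            scaf = index.target[scaf_name]
            # window must allow the whole query to land
            wlo = max(0, local_lo - qlo - pad)
            whi = min(len(scaf.sequence), local_lo + (thi - tlo)
                      + (qlen - qhi) + pad)
            window = scaf.sequence[wlo:whi]
            res = edlib.align(qseq, window, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            loc0, loc1 = res["locations"][0]
            matches, cols = edlib_stats(res["cigar"])
            tstart, tend = wlo + loc0, wlo + loc1 + 1
            qs, qe = 0, qlen  # HW aligns the full query
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            score = matches - 4 * (cols - matches)
            if score <= 0:
                continue
            records.append(AlignmentRecord(
                query_name=query_name, query_start=qs, query_end=qe,
                query_len=qlen, target_name=scaf_name, target_start=tstart,
                target_end=tend, target_len=len(scaf.sequence),
                strand=strand, matches=matches, aligned_columns=cols,
                score=float(score), cigar=res["cigar"]))
    records.sort(key=lambda r: -r.score)
    return _dedupe(records)


def _dedupe(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Drop hits whose target interval mostly repeats a better hit."""
    kept: list[AlignmentRecord] = []
    for r in records:
        dup = False
        for q in kept:
            if q.target_name != r.target_name or q.strand != r.strand:
                continue
            lo = max(q.target_start, r.target_start)
            hi = min(q.target_end, r.target_end)
            if hi - lo > 0.5 * (r.target_end - r.target_start):
                dup = True
                break
        if not dup:
            kept.append(r)
    return kept


def is_unique(hits: list[AlignmentRecord], margin: float = 0.20) -> bool:
    """True when the best hit's score exceeds the runner-up by ``margin``
    (a fraction of the best score) — the standard score-gap uniqueness proxy."""
    if not hits:
        return False
    if len(hits) == 1:
        return True
    best, second = hits[0].score, hits[1].score
    return best > 0 and (best - second) >= margin * best
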