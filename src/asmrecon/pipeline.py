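"""End-to-end synthetic evaluations: each function builds a seeded fixture
with the simulator, runs one pipeline stage on it, and scores the result
against the planted ground truth. Used by the demo subcommand and by the
reproduction script."""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import breakfix, gappatch, polish, segdup, stats
from .core import Assembly, BedInterval, ToolConfig
from .simulate import (DupSpec, ErrorPlan, GapPlan, MisjoinPlan, SimConfig,
                       derive_assembly, make_genome, simulate_end_pairs,
                       simulate_reads, write_sam)


def _seed(base: int, salt: int) -> int:
    return (base * 1_000_003 + salt) % 2**31


# ---------------------------------------------------------------------------
# gap patch round-trip


def patch_roundtrip_metrics(seed: int = 0, genome_len: int = 5_000_000,
                            n_gaps: int = 100, neg_frac: float = 0.15) -> dict:
    """Plant gaps into a genome, patch the gapped assembly against that
    same genome as donor, and check base-identical restoration."""
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 1),
                    gaps=GapPlan(count=n_gaps, neg_frac=neg_frac))
    genome, feats = make_genome(sim)
    derived, truth = derive_assembly(genome, sim, feats)
    cfg = ToolConfig()
    patches, verdicts = gappatch.build_patches(derived, genome, cfg)
    patched, report = gappatch.apply_patches(derived, patches)
    n_restored = _count_restored(patched, genome, truth, report["applied"])
    return {
        "n_gaps": len(truth.gaps),
        "n_patchable": len(patches),
        "n_applied": len(report["applied"]),
        "n_restored": n_restored,
        "restore_rate": n_restored / len(truth.gaps) if truth.gaps else 0.0,
        "sequence_identical_to_genome": all(
            patched[s.name].sequence == s.sequence for s in genome),
    }


def _count_restored(patched: Assembly, genome: Assembly, truth,
                    applied: list) -> int:
    """Per-gap base-identity check of applied patches, walking cumulative
    coordinate shifts left to right."""
    by_scaf: dict[str, list] = {}
    for p in applied:
        by_scaf.setdefault(p.gap.scaffold, []).append(p)
    spec_by_pos = {(t.scaffold, t.start): s
                   for t, s in zip(
                       sorted(truth.gaps, key=lambda t: (t.scaffold, t.start)),
                       sorted(truth.gap_specs,
                              key=lambda s: (s.scaffold, s.pos)))}
    n_ok = 0
    for scaf_name, ops in by_scaf.items():
        pseq = patched[scaf_name].sequence
        gseq = genome[scaf_name].sequence
        delta = 0
        for p in sorted(ops, key=lambda p: p.gap.start):
            spec = spec_by_pos[(scaf_name, p.gap.start)]
            new_start = p.gap.start + delta
            if spec.fill_len > 0:
                want = gseq[spec.pos:spec.pos + spec.fill_len]
                got = pseq[new_start:new_start + spec.fill_len]
            else:
                o = -spec.fill_len
                want = gseq[spec.pos + o - 25:spec.pos + o + 25]
                got = pseq[new_start - 25:new_start + 25]
            if want == got:
                n_ok += 1
            delta += p.length_delta
    return n_ok


# ---------------------------------------------------------------------------
# closure accounting


def closure_metrics(seed: int = 0, genome_len: int = 2_000_000,
                    n_gaps: int = 100, n_still_open: int = 20) -> dict:
    """Old assembly with n_gaps planted gaps vs a new assembly in which
    all but n_still_open of the same gaps are closed."""
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 2),
                    gaps=GapPlan(count=n_gaps, neg_frac=0.1))
    genome, feats = make_genome(sim)
    old_asm, old_truth = derive_assembly(genome, sim, feats)
    specs = sorted(old_truth.gap_specs, key=lambda s: (s.scaffold, s.pos))
    rng = np.random.default_rng(_seed(seed, 3))
    open_idx = set(rng.choice(len(specs), size=n_still_open, replace=False)
                   .tolist())
    still_open = [s for i, s in enumerate(specs) if i in open_idx]
    sim_new = SimConfig(genome_len=genome_len, seed=_seed(seed, 4))
    new_asm, _ = derive_assembly(genome, sim_new, feats,
                                 gap_specs=still_open)
    summary = gappatch.closure_accounting(old_asm, new_asm)
    return {
        "n_gaps": summary.n_gaps,
        "n_truly_filled": n_gaps - n_still_open,
        "n_filled": summary.n_filled,
        "fraction_filled": summary.fraction_filled,
        "total_fill_bp": summary.total_fill_bp,
        "true_fill_bp": sum(s.fill_len for i, s in enumerate(specs)
                            if i not in open_idx and s.fill_len > 0),
        "status_counts": dict(summary.status_counts),
        "n_negative_fills": int(sum(
            1 for v in summary.verdicts
            if v.status == gappatch.CLOSED and v.implied_fill_len < 0)),
    }


# ---------------------------------------------------------------------------
# misjoin detection


def pairs_from_simulated(sim_pairs) -> list[breakfix.EndPair]:
    out = []
    for p in sim_pairs:
        def end(scaf, pos, strand):
            if scaf is None:
                return None
            return breakfix.EndMapping(scaf, pos, pos + p.end_len, strand)
        out.append(breakfix.EndPair(
            p.pair_id, end(p.scaffold_a, p.pos_a, p.strand_a),
            end(p.scaffold_b, p.pos_b, p.strand_b)))
    return out


def breakfix_metrics(seed: int = 0, genome_len: int = 3_000_000,
                     inversions: int = 5, phys_coverage: float = 6.0,
                     tolerance: int = 5000) -> dict:
    """Plant inversions (two junctions each), simulate fosmid-scale end
    pairs at the given physical coverage, and score break calls against
    the true junctions."""
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 5),
                    misjoins=MisjoinPlan(inversions=inversions),
                    feature_margin=10_000)
    genome, feats = make_genome(sim)
    derived, truth = derive_assembly(genome, sim, feats)
    cfg = ToolConfig()
    sim_pairs = simulate_end_pairs(
        genome, truth, insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd,
        phys_coverage=phys_coverage, chimera_rate=0.0, end_len=600,
        seed=_seed(seed, 6))
    pairs = pairs_from_simulated(sim_pairs)
    model = breakfix.fit_insert_model(pairs, cfg)
    obs = breakfix.classify_pairs(pairs, model, cfg)
    calls = breakfix.call_breaks(obs, derived, cfg)
    junctions = truth.junctions
    hit = set()
    false_calls = 0
    errors = []
    for c in calls:
        # a call corresponds to a junction when its break interval
        # contains it or its chosen breakpoint lands within the tolerance
        near = [(abs(c.chosen_breakpoint - pos), i)
                for i, (scaf, pos) in enumerate(junctions)
                if scaf == c.scaffold
                and (abs(c.chosen_breakpoint - pos) <= tolerance
                     or c.break_start <= pos <= c.break_end)]
        if near:
            d, i = min(near)
            hit.add(i)
            errors.append(d)
        else:
            false_calls += 1
    return {
        "n_junctions": len(junctions),
        "n_pairs": len(pairs),
        "n_calls": len(calls),
        "recall": len(hit) / len(junctions) if junctions else 1.0,
        "false_positives": false_calls,
        "mean_breakpoint_error_bp": float(np.mean(errors)) if errors else 0.0,
        "breakpoint_errors_bp": errors,
        "insert_model": (model.mean, model.sd),
    }


def breakfix_null_metrics(seed: int = 0, genome_len: int = 2_000_000,
                          phys_coverage: float = 6.0) -> dict:
    """False-positive control: a correct assembly should yield no calls."""
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 7))
    genome, _ = make_genome(sim)
    cfg = ToolConfig()
    sim_pairs = simulate_end_pairs(genome, None, cfg.insert_mean,
                                   cfg.insert_sd, phys_coverage,
                                   seed=_seed(seed, 8))
    pairs = pairs_from_simulated(sim_pairs)
    model = breakfix.fit_insert_model(pairs, cfg)
    obs = breakfix.classify_pairs(pairs, model, cfg)
    calls = breakfix.call_breaks(obs, genome, cfg)
    conc = sum(1 for o in obs if o.verdict == breakfix.CONCORDANT)
    return {"n_pairs": len(pairs), "concordant_fraction": conc / len(pairs),
            "n_calls": len(calls)}


# ---------------------------------------------------------------------------
# polishing


def polish_metrics(seed: int = 0, genome_len: int = 400_000,
                   n_subs: int = 600, n_indels: int = 400,
                   n_six_bp: int = 5, coverage: float = 30.0,
                   max_rounds: int = 3) -> dict:
    """Plant small errors, polish with error-free reads, and score reverted
    errors, false edits, and the <6 bp indel exclusion boundary.

    Polishing runs map/pileup/integrate rounds until no further edits are
    called (multi-base indels can need two passes when read alignments
    fragment them). Scoring compares the result against the corrected
    target: the draft with every eligible (< 6 bp) error fixed and every
    oversize error deliberately left in place.
    """
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 9),
                    gaps=GapPlan(count=4),
                    errors=ErrorPlan(substitutions=n_subs, indels=n_indels,
                                     extra_indel_lens=(6,) * n_six_bp),
                    feature_margin=1500)
    genome, feats = make_genome(sim)
    derived, truth = derive_assembly(genome, sim, feats)
    reads = simulate_reads(genome, truth, target=derived, coverage=coverage,
                           read_len=100, seed=_seed(seed, 10), refine=True)
    cfg = ToolConfig()
    asm = derived
    current = reads
    n_applied = 0
    rounds = 0
    for _ in range(max_rounds):
        with tempfile.TemporaryDirectory() as tmp:
            sam = write_sam(current, asm, Path(tmp) / "reads.sam")
            pile = polish.pileup_sites(sam, asm, cfg)
        edits = polish.call_edits(pile, cfg)
        if not edits:
            break
        asm, report = polish.integrate_edits(asm, edits)
        applied = report["applied"]
        n_applied += len(applied)
        rounds += 1
        current = _update_placements(current, applied, asm)

    eligible = [e for e in truth.errors
                if max(len(e.ref), len(e.alt)) <= cfg.max_indel_edit]
    oversize = [e for e in truth.errors
                if max(len(e.ref), len(e.alt)) > cfg.max_indel_edit]
    target, _ = polish.integrate_edits(derived, eligible)
    n_reverted = _count_present(asm, target, eligible, derived=False)
    oversize_touched = len(oversize) - _count_present(asm, derived, oversize,
                                                      derived=True)
    identical = all(asm[s.name].sequence == s.sequence for s in target)
    return {
        "n_planted": len(eligible),
        "n_oversize_planted": len(oversize),
        "n_edits_applied": n_applied,
        "rounds": rounds,
        "n_reverted": n_reverted,
        "revert_rate": n_reverted / len(eligible) if eligible else 1.0,
        "false_edits": 0 if identical else _residual_false_bp(
            asm, target, eligible, n_reverted),
        "oversize_indels_edited": oversize_touched,
        "identical_to_target": identical,
        "n_reads": len(reads),
    }


def _update_placements(placements, applied, new_asm):
    """Carry read placements across an integration round: shift starts by
    the cumulative length change of edits to their left, and re-align
    (edlib) only the reads overlapping an edited region."""
    import edlib

    from .align import edlib_stats
    from .simulate import ReadPlacement

    by_scaf: dict[str, list] = {}
    for e in applied:
        by_scaf.setdefault(e.scaffold, []).append(e)
    pos_map = {}
    hot = {}
    for name, edits in by_scaf.items():
        edits.sort(key=lambda e: e.position)
        pos = np.array([e.position for e in edits])
        cum = np.cumsum([e.length_delta for e in edits])
        pos_map[name] = (pos, cum)
        hot[name] = [(e.position - 150, e.position + len(e.ref) + 150)
                     for e in edits]
    seqs = {s.name: s.sequence for s in new_asm}
    out = []
    for r in placements:
        if r.scaffold not in pos_map:
            out.append(r)
            continue
        pos, cum = pos_map[r.scaffold]
        i = int(np.searchsorted(pos, r.start, side="left")) - 1
        shift = int(cum[i]) if i >= 0 else 0
        touched = any(lo < r.end and hi > r.start
                      for lo, hi in hot[r.scaffold])
        if not touched:
            out.append(ReadPlacement(r.name, r.scaffold, r.start + shift,
                                     r.end + shift, r.strand, r.seq,
                                     r.cigar, r.nm, r.identity))
            continue
        tseq = seqs[r.scaffold]
        lo = max(0, r.start + shift - 24)
        hi = min(len(tseq), r.start + shift + len(r.seq) + 24)
        res = edlib.align(r.seq, tseq[lo:hi], mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        l0, l1 = res["locations"][0]
        matches, cols = edlib_stats(res["cigar"])
        out.append(ReadPlacement(r.name, r.scaffold, lo + l0, lo + l1 + 1,
                                 r.strand, r.seq, res["cigar"],
                                 res["editDistance"], matches / cols))
    out.sort(key=lambda p: (p.scaffold, p.start))
    return out


def _count_present(asm: Assembly, reference: Assembly, errors,
                   derived: bool) -> int:
    """How many error loci look like ``reference`` in ``asm``: each error's
    unique local window from the reference sequence is searched in the
    polished assembly (alignment may shift an equivalent repair, so exact
    coordinates cannot be assumed)."""
    by_scaf: dict[str, list] = {}
    for e in errors:
        by_scaf.setdefault(e.scaffold, []).append(e)
    n = 0
    for name, errs in by_scaf.items():
        rseq = reference[name].sequence
        aseq = asm[name].sequence
        errs.sort(key=lambda e: e.position)
        # reference coords of each error after the edits before it
        delta = 0
        for e in errs:
            pos = e.position + (delta if not derived else 0)
            lo = max(0, pos - 30)
            hi = min(len(rseq), pos + max(len(e.ref), len(e.alt)) + 30)
            if aseq.find(rseq[lo:hi]) >= 0:
                n += 1
            if not derived:
                delta += e.length_delta
    return n


def _residual_false_bp(asm: Assembly, target: Assembly, eligible,
                       n_reverted: int) -> int:
    """Upper bound on spurious changes: edit distance to the corrected
    target beyond what the unreverted planted errors account for."""
    import edlib

    dist = 0
    for s in target:
        dist += edlib.align(asm[s.name].sequence, s.sequence, mode="NW",
                            task="distance")["editDistance"]
    unrev_bp = (len(eligible) - n_reverted) * 6  # per-error allowance
    return max(0, dist - unrev_bp)


# ---------------------------------------------------------------------------
# segmental duplications


def wgac_metrics(seed: int = 0, genome_len: int = 600_000) -> dict:
    """Threshold behavior of the assembly self-comparison: a 2 kbp / 98%
    duplication is called, 800 bp / 98% fails the length rule, 2 kbp / 85%
    fails the identity rule."""
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 11),
                    duplications=[DupSpec(2000, 0.98),
                                  DupSpec(800, 0.98),
                                  DupSpec(2000, 0.85)])
    genome, feats = make_genome(sim)
    calls, nr = segdup.wgac_self_compare(genome, [], ToolConfig())

    def covered(dup, frac=0.5) -> bool:
        want = [dup.src, dup.dst]
        ok = 0
        for lo, hi in want:
            cov = sum(min(hi, e) - max(lo, s)
                      for s, e in nr.get(dup.scaffold, [])
                      if e > lo and s < hi)
            ok += cov >= frac * (hi - lo)
        return ok == 2

    d2k98, d800, d2k85 = feats.duplications
    det_ident = [c.identity for c in calls
                 if _overlap_frac(c, d2k98) > 0.5]
    bp, frac = segdup.nonredundant_bp(nr, genome)
    return {
        "called_2kbp_98": covered(d2k98),
        "called_800bp_98": covered(d800),
        "called_2kbp_85": covered(d2k85),
        "n_redundant_pairs": len(calls),
        "detected_identity": float(np.mean(det_ident)) if det_ident else 0.0,
        "nonredundant_bp": bp,
        "nonredundant_frac": frac,
    }


def _overlap_frac(call, dup) -> float:
    for lo, hi in (dup.src, dup.dst):
        ov = min(call.end, hi) - max(call.start, lo)
        if call.scaffold == dup.scaffold and ov > 0:
            return ov / (hi - lo)
    return 0.0


def wssd_metrics(seed: int = 0, genome_len: int = 1_000_000,
                 coverage: float = 10.0) -> dict:
    """Collapsed-duplication detection by read depth: a 20 kbp collapse is
    called with high reciprocal overlap; an 8 kbp collapse stays below the
    10 kbp call threshold."""
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 12),
                    duplications=[DupSpec(20_000, 0.99, collapsed=True),
                                  DupSpec(8_000, 0.99, collapsed=True)],
                    feature_margin=25_000)
    genome, feats = make_genome(sim)
    derived, truth = derive_assembly(genome, sim, feats)
    reads = simulate_reads(genome, truth, target=derived, coverage=coverage,
                           read_len=100, seed=_seed(seed, 13))
    cfg = ToolConfig()
    _, wgac_nr = segdup.wgac_self_compare(derived, [], cfg)
    uniq = segdup.default_unique_regions(derived, wgac_nr, cfg)
    profile = segdup.wssd_depth(reads, derived, uniq, cfg)
    calls = segdup.wssd_call(profile, cfg)

    def derived_interval(dup):
        m0 = truth.map_genome(dup.scaffold, dup.src[0])
        m1 = truth.map_genome(dup.scaffold, dup.src[1] - 1)
        return m0[0], m0[1], m1[1] + 1

    big = derived_interval(feats.duplications[0])
    small = derived_interval(feats.duplications[1])

    def reciprocal(call, iv):
        if call.scaffold != iv[0]:
            return 0.0
        ov = min(call.end, iv[2]) - max(call.start, iv[1])
        if ov <= 0:
            return 0.0
        return min(ov / (iv[2] - iv[1]), ov / call.length)

    best_big = max((reciprocal(c, big) for c in calls), default=0.0)
    small_called = any(reciprocal(c, small) > 0.2 for c in calls)
    return {
        "n_calls": len(calls),
        "big_reciprocal_overlap": best_big,
        "small_called": small_called,
        "unique_mean_depth": profile.unique_mean,
        "unique_sd": profile.unique_sd,
    }


def wssd_null_calls(seed: int = 0, genome_len: int = 600_000,
                    coverage: float = 10.0) -> int:
    """Number of WSSD calls on a duplication-free genome (expected 0)."""
    sim = SimConfig(genome_len=genome_len, seed=_seed(seed, 14))
    genome, _ = make_genome(sim)
    reads = simulate_reads(genome, None, target=genome, coverage=coverage,
                           read_len=100, seed=_seed(seed, 15))
    cfg = ToolConfig()
    uniq = [BedInterval(s.name, 0, len(s)) for s in genome]
    profile = segdup.wssd_depth(reads, genome, uniq, cfg)
    return len(segdup.wssd_call(profile, cfg))


# ---------------------------------------------------------------------------
# permutation test


def permutation_planted_p(seed: int = 0, reps: int = 9999) -> dict:
    """Planted full-containment fixture: features cover 10% of the
    universe, every query interval lies inside a feature; the empirical P
    must bottom out at 1/(reps+1)."""
    rng = np.random.default_rng(_seed(seed, 16))
    universe = [BedInterval("chr1", 0, 200_000)]
    feats = [BedInterval("chr1", s, s + 2000, "feat")
             for s in range(0, 200_000, 20_000)]
    query = []
    for _ in range(30):
        f = feats[rng.integers(len(feats))]
        q0 = int(rng.integers(f.start, f.end - 200))
        query.append(BedInterval("chr1", q0, q0 + 200, "q"))
    cfg = ToolConfig(perm_reps=reps, rng_seed=_seed(seed, 17))
    res = stats.permutation_enrichment(query, feats, universe, cfg)
    return {"empirical_p": res.empirical_p,
            "observed": res.observed_overlap_fraction,
            "null_mean": res.null_mean, "reps": res.reps}


def permutation_null_rejection(seed: int = 0, trials: int = 1000,
                               reps: int = 199, alpha: float = 0.05) -> dict:
    """Calibration under the null: query intervals drawn from the same
    placement distribution as the permutation null must reject at ~alpha.

    Uses the bp-overlap statistic, which is close to continuous; the
    default interval-count statistic is discrete and its >= tie handling
    makes it deliberately conservative, which would bias this calibration
    check below alpha.
    """
    rng = np.random.default_rng(_seed(seed, 18))
    universe = [BedInterval("chr1", 0, 100_000)]
    feats = [BedInterval("chr1", s, s + 1000, "feat")
             for s in range(0, 100_000, 10_000)]
    rejections = 0
    for t in range(trials):
        query = []
        for _ in range(40):
            q0 = int(rng.integers(0, 100_000 - 150))
            query.append(BedInterval("chr1", q0, q0 + 150, "q"))
        cfg = ToolConfig(perm_reps=reps, rng_seed=int(rng.integers(2**31)))
        res = stats.permutation_enrichment(query, feats, universe, cfg,
                                           statistic="bp-overlap")
        rejections += res.empirical_p <= alpha
    return {"trials": trials, "rejection_rate": rejections / trials,
            "binomial_sd": float(np.sqrt(alpha * (1 - alpha) / trials))}


# ---------------------------------------------------------------------------
# demo


def demo_scorecard(seed: int = 0) -> dict:
    """Compact end-to-end run over all stages (smaller fixtures than the
    reproduction script) with a truth-vs-called scorecard."""
    card: dict = {}
    card["patch"] = patch_roundtrip_metrics(seed, genome_len=1_000_000,
                                            n_gaps=30)
    card["closure"] = closure_metrics(seed, genome_len=1_000_000,
                                      n_gaps=40, n_still_open=10)
    card["breaks"] = breakfix_metrics(seed, genome_len=2_000_000,
                                      inversions=3)
    card["polish"] = polish_metrics(seed, genome_len=200_000, n_subs=150,
                                    n_indels=100, n_six_bp=3)
    card["wgac"] = wgac_metrics(seed, genome_len=400_000)
    card["wssd"] = wssd_metrics(seed, genome_len=800_000)
    card["permutation"] = permutation_planted_p(seed, reps=999)
    return card
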