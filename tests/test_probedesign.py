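"""Probe-candidate selection: spacing, flanks, trimming, uniqueness,
ambiguity, density balancing, preselection rounds and panel assembly."""

import numpy as np
import pytest

from chipforge.attrition import Ledger
from chipforge.probedesign import (
    ProbeCandidate,
    RoundSpec,
    assemble_panel,
    candidates_from_callset,
    classify_ambiguity,
    density_adjust,
    extract_flanks,
    flank_uniqueness,
    panel_to_fasta,
    panel_to_tsv,
    preselect,
    spacing_filter,
    trim_flank_n_runs,
)

from conftest import make_callset


def cs_at(positions, chrom="chr1"):
    return make_callset(
        [(chrom, p, "A", ("G",), [(0, 1)]) for p in positions], ["S1"]
    )


class TestSpacing:
    def test_close_pair_knocks_both_out(self):
        out = spacing_filter(cs_at([100, 140, 300]), min_distance=50)
        assert [r.pos for r in out.records] == [300]

    def test_boundary_distance_kept(self):
        out = spacing_filter(cs_at([100, 150]), min_distance=50)
        assert [r.pos for r in out.records] == [100, 150]

    def test_single_site_kept(self):
        out = spacing_filter(cs_at([42]), min_distance=50)
        assert [r.pos for r in out.records] == [42]

    def test_distance_measured_against_full_catalogue(self):
        # 100 and 140 knock each other out; 180 is 40 from 140 (removed
        # from output but still in the catalogue), so 180 is removed too
        out = spacing_filter(cs_at([100, 140, 180]), min_distance=50)
        assert [r.pos for r in out.records] == []

    def test_matches_all_pairs_oracle(self, rng):
        pos = np.sort(rng.choice(200_000, size=5000, replace=False)) + 1
        cs = cs_at(pos.tolist())
        out = spacing_filter(cs, min_distance=50)
        keep = set()
        for i, p in enumerate(pos):
            d = np.abs(pos - p)
            d[i] = 10**9
            if d.min() >= 50:
                keep.add(int(p))
        assert {r.pos for r in out.records} == keep


class TestFlanks:
    def test_full_left_flank(self):
        ref = {"chr1": "A" * 200}
        r = cs_at([51]).records[0]
        left, right = extract_flanks(ref, r)
        assert len(left) == 50 and len(right) == 50

    def test_truncated_left_flank(self):
        ref = {"chr1": "A" * 200}
        r = cs_at([10]).records[0]
        left, right = extract_flanks(ref, r)
        assert len(left) == 9 and len(right) == 50

    def test_matches_slicing_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        ref = {"chr1": seq}
        for _ in range(50):
            p = int(rng.integers(1, 1001))
            r = cs_at([p]).records[0]
            left, right = extract_flanks(ref, r)
            assert left == seq[max(0, p - 51): p - 1]
            assert right == seq[p: p + 50]
            assert left + seq[p - 1] + right in seq

    def test_beyond_end_rejected(self):
        with pytest.raises(IndexError):
            extract_flanks({"chr1": "ACGT"}, cs_at([10]).records[0])


class TestTrimming:
    def test_left_run_trimmed_keep(self):
        left = "C" * 16 + "NNNN" + "G" * 30  # long N run 30 bp from variant
        right = "T" * 50
        tl, tr, keep = trim_flank_n_runs(left, right)
        assert tl == "G" * 30 and tr == right and keep

    def test_both_sides_trimmed_rejected(self):
        left = "C" * 10 + "NNNN" + "G" * 30
        right = "T" * 30 + "NNNNN" + "A" * 10
        tl, tr, keep = trim_flank_n_runs(left, right)
        assert (len(tl), len(tr)) == (30, 30) and not keep

    def test_short_n_runs_untouched(self):
        left = "C" * 20 + "NNN" + "G" * 27  # run of exactly 3 is allowed
        right = "T" * 50
        tl, tr, keep = trim_flank_n_runs(left, right)
        assert tl == left and keep

    def test_short_side_boundary(self):
        # trimmed short side of exactly min_short passes, one less fails
        right = "T" * 50
        left20 = "N" * 5 + "G" * 20
        assert trim_flank_n_runs(left20, right)[2]
        left19 = "N" * 5 + "G" * 19
        assert not trim_flank_n_runs(left19, right)[2]


class TestAmbiguity:
    def test_enumeration_exactly_four(self):
        bases = "ACGT"
        amb = [(r, a) for r in bases for a in bases if r != a
               and classify_ambiguity(r, a)]
        assert sorted(amb) == [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")]

    def test_transitions_not_ambiguous(self):
        assert not classify_ambiguity("A", "G")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_ambiguity("N", "A")


class TestUniqueness:
    def _candidate(self, ref, pos, chrom="chr1", flank=50):
        r = cs_at([pos], chrom).records[0]
        left, right = extract_flanks(ref, r, flank)
        return ProbeCandidate(chrom=chrom, pos=pos, ref="A", alt="G",
                              left_flank=left, right_flank=right)

    def test_unique_in_random_genome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        ref = {"chr1": seq}
        res = flank_uniqueness(self._candidate(ref, 2500), ref)
        assert res.unique and res.side in ("left", "right")

    def test_exact_duplicate_copy_fails(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=300))
        filler = "".join(rng.choice(list("ACGT"), size=1000))
        seq = core + filler + core  # exact duplicated segment
        ref = {"chr1": seq}
        res = flank_uniqueness(self._candidate(ref, 150), ref)
        assert not res.unique

    def test_both_flanks_short_is_reasoned_false(self):
        cand = ProbeCandidate(chrom="chr1", pos=5, ref="A", alt="G",
                              left_flank="ACG", right_flank="TTG")
        res = flank_uniqueness(cand, {"chr1": "A" * 100})
        assert not res.unique and "shorter" in res.reason

    def test_near_duplicate_exact_vs_scored(self, rng):
        """A copy with 2 mismatches inside the probe passes exact search
        but the scored mode still calls it unique only because the true
        locus out-scores the decoy; an exact decoy fails both."""
        rng2 = np.random.default_rng(77)
        seq = list("".join(rng2.choice(list("ACGT"), size=4000)))
        probe_region = seq[1000:1071]
        decoy = probe_region.copy()
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        decoy[10] = swap[decoy[10]]
        decoy[30] = swap[decoy[30]]
        seq[3000:3071] = decoy
        ref = {"chr1": "".join(seq)}
        cand = self._candidate(ref, 1036)
        assert flank_uniqueness(cand, ref, mode="exact").unique
        scored = flank_uniqueness(cand, ref, mode="scored")
        assert scored.unique  # mismatch penalty separates the decoy

    def test_synthetic_duplicated_segments_never_unique(self, small_cohort):
        """Every probe anchored inside an exact duplicated segment longer
        than the probe must fail the uniqueness check."""
        cfg, ref, haps, dh = small_cohort
        checked = 0
        for r in dh.records[:400]:
            z = r.pos - 1
            # deep inside a duplicated copy: both flanks within the segment
            inside = any(
                c == r.chrom and s + 60 <= z < e - 60
                for c, s, e in ref.duplicated
            )
            if not inside:
                continue
            left, right = extract_flanks(ref.sequences, r)
            cand = ProbeCandidate(chrom=r.chrom, pos=r.pos, ref="A", alt="G",
                                  left_flank=left, right_flank=right)
            assert not flank_uniqueness(cand, ref.sequences).unique
            checked += 1
        assert checked > 0


def cand(pos, maf, chrom="chr1", **kw):
    defaults = dict(ref="A", alt="G", left_flank="C" * 50,
                    right_flank="T" * 50, unique=True, het_dh_lines=0)
    defaults.update(kw)
    return ProbeCandidate(chrom=chrom, pos=pos,
                          maf_by_population=dict(maf), **defaults)


class TestDensityAdjust:
    def test_overfull_window_filtered_by_maf(self, rng):
        cands = [
            cand(int(p), {"A": 0.30 if i < 10 else 0.05})
            for i, p in enumerate(rng.choice(99_000, 31, replace=False) + 1)
        ]
        out = density_adjust(cands)
        assert len(out) == 10 and all(c.max_maf >= 0.15 for c in out)

    def test_exactly_thirty_untouched(self, rng):
        cands = [cand(int(p), {"A": 0.02})
                 for p in rng.choice(99_000, 30, replace=False) + 1]
        assert len(density_adjust(cands)) == 30

    def test_empty(self):
        assert density_adjust([]) == []

    def test_idempotent_and_matches_window_oracle(self, rng):
        cands = [
            cand(int(p) + 1, {"A": float(rng.uniform(0, 0.5))},
                 chrom=f"chr{1 + int(p) % 2}")
            for p in rng.choice(500_000, 800, replace=False)
        ]
        out = density_adjust(cands)
        # brute-force oracle
        from collections import Counter
        win = Counter((c.chrom, (c.pos - 1) // 100_000) for c in cands)
        oracle = [
            c for c in cands
            if win[(c.chrom, (c.pos - 1) // 100_000)] <= 30
            or c.max_maf >= 0.15
        ]
        assert [c.key for c in out] == [c.key for c in oracle]
        again = density_adjust(out)
        assert [c.key for c in again] == [c.key for c in out]

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            density_adjust([], window=0)


class TestPreselect:
    def test_round1_vs_round2_maf_rules(self):
        round1 = RoundSpec(maf_floors={"USDA": 0.10, "INRAE": 0.10},
                           quantifier="all")
        round2 = RoundSpec(maf_floors={"INRAE": 0.10})
        c_mixed = cand(100, {"USDA": 0.12, "INRAE": 0.08})
        c_inrae = cand(200, {"USDA": 0.02, "INRAE": 0.12})
        assert preselect([c_mixed], round1) == []
        assert preselect([c_mixed], round2) == []
        assert preselect([c_inrae], round2) == [c_inrae]
        assert preselect([c_inrae], round1) == []

    def test_unicity_failure_rejected_in_both_rounds(self):
        c = cand(100, {"USDA": 0.3, "INRAE": 0.3}, unique=False)
        for spec in (RoundSpec(maf_floors={"USDA": 0.1, "INRAE": 0.1}),
                     RoundSpec(maf_floors={"INRAE": 0.1})):
            assert preselect([c], spec) == []

    def test_het_line_cap(self):
        spec = RoundSpec(maf_floors={"INRAE": 0.1}, max_het_lines=4)
        assert preselect([cand(1, {"INRAE": 0.3}, het_dh_lines=4)], spec)
        assert not preselect([cand(1, {"INRAE": 0.3}, het_dh_lines=5)], spec)

    def test_empty_input(self):
        assert preselect([], RoundSpec(maf_floors={})) == []

    def test_unknown_population_rejected(self):
        with pytest.raises(KeyError):
            preselect([cand(1, {"A": 0.5})], RoundSpec(maf_floors={"B": 0.1}))

    def test_attrition_ledger_sums(self, rng):
        cands = [
            cand(int(p) + 1, {"INRAE": float(rng.uniform(0, 0.5))},
                 unique=bool(rng.random() < 0.8),
                 het_dh_lines=int(rng.integers(0, 8)))
            for p in rng.choice(10_000, 200, replace=False)
        ]
        led = Ledger()
        out = preselect(cands, RoundSpec(maf_floors={"INRAE": 0.1}),
                        ledger=led)
        led.check()
        removed = sum(n_in - n_out for _, n_in, n_out in led.stages)
        assert removed + len(out) == len(cands)


class TestPanel:
    def test_legacy_dedup_and_not_recommended(self):
        sel = [cand(100, {"A": 0.3}), cand(200, {"A": 0.3})]
        legacy = [cand(100, {"A": 0.3}, legacy=True)]
        designability = {sel[1].key: "not_recommended"}
        panel = assemble_panel(sel, legacy, designability)
        assert len(panel) == 1
        assert panel[0].pos == 100 and panel[0].legacy

    def test_ambiguous_excluded_unless_legacy(self):
        sel = [cand(100, {"A": 0.3}, ref="A", alt="T", ambiguous=True)]
        legacy = [cand(200, {"A": 0.3}, ref="C", alt="G", ambiguous=True)]
        panel = assemble_panel(sel, legacy)
        assert [c.pos for c in panel] == [200]

    def test_set_algebra_oracle(self, rng):
        sel = [cand(int(p) + 1, {"A": 0.3}) for p in range(100)]
        legacy = [cand(int(p) + 1, {"A": 0.3}) for p in range(80, 100)]
        bad = {c.key: "not_recommended" for c in sel[:10]}
        panel = assemble_panel(sel, legacy, bad)
        oracle = {c.key for c in sel} | {c.key for c in legacy}
        oracle -= set(bad)
        assert {c.key for c in panel} == oracle
        assert sum(c.legacy for c in panel) == 20

    def test_writers_smoke(self, tmp_path):
        panel = assemble_panel([cand(100, {"A": 0.3})], [])
        panel_to_tsv(panel, str(tmp_path / "p.tsv"))
        panel_to_fasta(panel, str(tmp_path / "p.fa"))
        fa = (tmp_path / "p.fa").read_text()
        assert "[A/G]" in fa and fa.startswith(">chr1_100_A_G")


def test_candidates_from_callset_end_to_end(small_cohort):
    cfg, ref, haps, dh = small_cohort
    cands = candidates_from_callset(dh, ref.sequences)
    assert cands
    for c in cands[:20]:
        assert len(c.left_flank) <= 50 and len(c.right_flank) <= 50
        seq = ref.sequences[c.chrom]
        assert c.right_flank == seq[c.pos: c.pos + 50]


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st

_flank = st.text(alphabet="ACGTN", min_size=0, max_size=50)


@settings(max_examples=200, derandomize=True)
@given(left=_flank, right=_flank)
def test_trimming_properties(left, right):
    """Trimmed flanks are variant-proximal sub-strings free of long N runs,
    and the keep verdict follows the shortest/longest length rule."""
    tl, tr, keep = trim_flank_n_runs(left, right)
    assert left.endswith(tl) and right.startswith(tr)
    assert "NNNN" not in tl and "NNNN" not in tr
    lens = sorted((len(tl), len(tr)))
    assert keep == (lens[0] >= 20 and lens[1] >= 50)


@settings(max_examples=50, derandomize=True)
@given(ref=st.sampled_from("ACGT"), alt=st.sampled_from("ACGT"))
def test_ambiguity_strand_flip_invariant(ref, alt):
    """Complementing both alleles never changes the ambiguity verdict."""
    if ref == alt:
        return
    comp = dict(zip("ACGT", "TGCA"))
    assert classify_ambiguity(ref, alt) == classify_ambiguity(
        comp[ref], comp[alt]
    )
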