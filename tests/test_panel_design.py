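"""Selection cascade: per-filter examples, scan oracles, greedy thinning
optimality, budget arithmetic, and ledger bookkeeping on the planted fixture."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplipanel import panel_design as pdn
from amplipanel.formats_io import MISSING, GenomicInterval, VariantRecord
from amplipanel.panel_design import DesignConfig, design_panel


def snv(pos, chrom="chr1", genotypes=(0, 1, 2, 1), depths=(10, 10, 10, 10),
        ref="A", alts=("G",), placed=True):
    return VariantRecord(chrom, pos, ref, alts, tuple(genotypes), tuple(depths),
                         placed=placed)


class TestRepeatFilter:
    def test_flank_boundary_hand_trace(self):
        # repeat [500, 600) 0-based, flank 200 -> expanded [300, 800);
        # a variant at 1-based 300 is 0-based 299, just outside
        repeat = [GenomicInterval("chr1", 500, 600)]
        kept, removed = pdn.filter_near_repeats([snv(300)], repeat, flank=200)
        assert len(kept) == 1 and removed == 0
        kept, removed = pdn.filter_near_repeats([snv(301)], repeat, flank=200)
        assert len(kept) == 0 and removed == 1

    def test_inside_repeat_removed(self):
        repeat = [GenomicInterval("chr1", 500, 600)]
        kept, removed = pdn.filter_near_repeats([snv(550)], repeat, flank=0)
        assert removed == 1

    def test_flank_zero_adjacent_retained(self):
        repeat = [GenomicInterval("chr1", 500, 600)]
        # 0-based 600 (1-based 601) is the first base after the interval
        kept, _ = pdn.filter_near_repeats([snv(601)], repeat, flank=0)
        assert len(kept) == 1

    def test_chrom_without_annotation_is_repeat_free(self):
        repeat = [GenomicInterval("chr2", 0, 1000)]
        kept, removed = pdn.filter_near_repeats([snv(500)], repeat, flank=200)
        assert len(kept) == 1 and removed == 0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        repeats = []
        for _ in range(20):
            s = int(rng.integers(0, 5000))
            repeats.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 100))))
        variants = [snv(int(p)) for p in rng.integers(1, 5200, size=200)]
        kept, removed = pdn.filter_near_repeats(variants, repeats, flank=50)
        expected = [
            v for v in variants
            if not any(iv.expanded(50).contains_pos1(v.pos) for iv in repeats)
        ]
        assert [v.pos for v in kept] == [v.pos for v in expected]
        assert removed == len(variants) - len(expected)


class TestSnvPrefilter:
    @pytest.mark.parametrize(
        "ref,alts,kept",
        [
            ("A", ("AT",), False),       # insertion
            ("AT", ("A",), False),       # deletion
            ("A", ("G",), True),         # SNV
            ("A", ("G", "T"), True),     # multiallelic SNV passes the prefilter
            ("A", ("G", "AT"), False),   # mixed SNV/indel alt set
        ],
    )
    def test_allele_length_cases(self, ref, alts, kept):
        out = pdn.filter_snv_biallelic_prefilter([snv(100, ref=ref, alts=alts)])
        assert bool(out) is kept


class TestMafDepthFilter:
    def test_maf_boundary_inclusive(self):
        # MAF exactly 0.2 is kept ("less than 0.2" is removed)
        v = snv(100, genotypes=(1, 1, 0, 0, 0, 0, 0, 0, 0, 0),
                depths=(30,) * 10)
        assert v.maf() == pytest.approx(0.1)
        kept, _ = pdn.filter_maf_depth([v], min_maf=0.2)
        assert not kept
        v = snv(100, genotypes=(1, 1, 1, 1, 0, 0, 0, 0, 0, 0), depths=(30,) * 10)
        assert v.maf() == pytest.approx(0.2)
        kept, _ = pdn.filter_maf_depth([v], min_maf=0.2)
        assert len(kept) == 1

    def test_depth_ceiling_exclusive(self):
        # mean depth exactly 60 is removed (">= 60x removed")
        v = snv(100, genotypes=(1,) * 20, depths=(60,) * 20)
        assert v.maf() == 0.5
        kept, _ = pdn.filter_maf_depth([v])
        assert not kept
        v = snv(100, genotypes=(1,) * 20, depths=(59,) * 20)
        kept, _ = pdn.filter_maf_depth([v])
        assert len(kept) == 1

    def test_all_het_retained(self):
        v = snv(100, genotypes=(1,) * 20, depths=(30,) * 20)
        kept, _ = pdn.filter_maf_depth([v])
        assert len(kept) == 1

    def test_uncalled_locus_counted_separately(self):
        v = snv(100, genotypes=(MISSING,) * 4)
        kept, n_uncalled = pdn.filter_maf_depth([v])
        assert not kept and n_uncalled == 1

    def test_missing_excluded_from_maf(self):
        v = snv(100, genotypes=(1, 1, MISSING, MISSING), depths=(10,) * 4)
        assert v.maf() == pytest.approx(0.5)


class TestPlacedAndSubsample:
    def test_placed_set(self):
        variants = [snv(1), snv(1, chrom="scaffold_102")]
        assert len(pdn.filter_placed(variants, {"chr1"})) == 1
        assert pdn.filter_placed(variants, set()) == []

    def test_placed_flag_fallback(self):
        variants = [snv(1, placed=True), snv(2, placed=False)]
        assert len(pdn.filter_placed(variants, None)) == 1

    def test_exact_count(self):
        variants = [snv(100 + i) for i in range(400)]
        out = pdn.subsample(variants, 0.0125, seed=0)
        assert len(out) == 5

    def test_identity_fraction(self):
        variants = [snv(100 + i) for i in range(10)]
        assert pdn.subsample(variants, 1.0, seed=0) == variants

    def test_deterministic_and_seed_sensitive(self):
        variants = [snv(100 + i) for i in range(200)]
        a = pdn.subsample(variants, 0.25, seed=5)
        b = pdn.subsample(variants, 0.25, seed=5)
        c = pdn.subsample(variants, 0.25, seed=6)
        assert a == b
        assert [v.pos for v in a] == sorted(v.pos for v in a)  # genome order kept
        assert a != c

    def test_zero_selection_errors(self):
        with pytest.raises(ValueError, match="larger fraction"):
            pdn.subsample([snv(1)], 0.01, seed=0)


def _homopolymer_oracle(seq, min_len):
    """Independent run-length-encoding scan."""
    seq = seq.upper()
    run, prev = 0, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if ch in "ACGT" and run >= min_len:
            return True
    return False


def _microsat_oracle(seq, min_units):
    seq = seq.upper()
    for unit in ("CA", "AC", "GT", "TG"):
        for start in range(len(seq)):
            count = 0
            i = start
            while seq[i : i + 2] == unit:
                count += 1
                i += 2
            if count >= min_units:
                return True
    return False


class TestContextScans:
    def test_poly_a_ten_fires(self):
        assert pdn.scan_homopolymer("ACGT" + "A" * 10 + "ACGT", 10) is not None

    def test_nine_below_threshold(self):
        assert pdn.scan_homopolymer("A" * 9, 10) is None

    def test_n_never_forms_a_run(self):
        assert pdn.scan_homopolymer("N" * 30, 10) is None

    def test_case_insensitive(self):
        # 'acgt' ends in t, so the run is 13 long starting at index 3
        assert pdn.scan_homopolymer("acgt" + "t" * 12, 10) == (3, 16)

    @settings(max_examples=300, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    def test_homopolymer_agrees_with_rle_oracle(self, seq):
        assert (pdn.scan_homopolymer(seq, 10) is not None) == _homopolymer_oracle(seq, 10)

    def test_ca_five_units(self):
        assert pdn.scan_microsatellite("CACACACACA", min_units=5) is not None

    def test_alternating_units_no_tandem(self):
        assert pdn.scan_microsatellite("CAGTCAGT", min_units=2) is None

    def test_empty_sequence(self):
        assert pdn.scan_microsatellite("", min_units=5) is None

    @settings(max_examples=300, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_microsat_agrees_with_oracle(self, seq):
        got = pdn.scan_microsatellite(seq, min_units=3) is not None
        assert got == _microsat_oracle(seq, 3)


class TestFilterContext:
    def _reference(self, motif, offset, length=2000):
        rng = np.random.default_rng(9)
        # scrubbed-free background built from a fixed repeating 4-mer so no
        # chance homopolymer/microsat can fire
        seq = list("ACGT" * (length // 4))
        seq[offset : offset + len(motif)] = list(motif)
        return {"chr1": "".join(seq)}

    def test_planted_poly_t_near_snp_removed(self):
        ref = self._reference("T" * 12, offset=1050)  # 50 bp from the SNP
        out = pdn.filter_context([snv(1001)], ref, context_flank=200)
        assert out == []

    def test_clean_window_retained(self):
        ref = {"chr1": "ACGT" * 500}
        assert len(pdn.filter_context([snv(1001)], ref, context_flank=200)) == 1

    def test_window_clip_at_edge(self):
        # poly-A of 10 straddling the window edge: only 9 bases inside -> no fire
        ref = self._reference("A" * 10, offset=1192)  # window is [800, 1201)
        assert len(pdn.filter_context([snv(1001)], ref, context_flank=200)) == 1
        # shifted one base left, 10 bases fall inside -> removed
        ref = self._reference("A" * 10, offset=1191)
        assert pdn.filter_context([snv(1001)], ref, context_flank=200) == []

    def test_position_beyond_contig_errors(self):
        with pytest.raises(ValueError, match="beyond contig"):
            pdn.filter_context([snv(5000)], {"chr1": "ACGT" * 100}, 200)


class TestThinning:
    def test_hand_trace(self):
        variants = [snv(p) for p in (100, 13100, 20100, 40200)]
        kept = pdn.thin_by_distance(variants, 20_000)
        assert [v.pos for v in kept] == [100, 20100, 40200]

    def test_single_variant_kept(self):
        variants = [snv(5, chrom="chr1"), snv(7, chrom="chr2")]
        assert pdn.thin_by_distance(variants, 20_000) == variants

    def test_greedy_is_optimal_vs_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            positions = sorted(int(p) for p in rng.integers(1, 200, size=12))
            variants = [snv(p) for p in dict.fromkeys(positions)]
            kept = pdn.thin_by_distance(variants, 30)
            # brute force: max feasible subset size by enumeration
            best = 0
            n = len(variants)
            for mask in range(1 << n):
                subset = [variants[i].pos for i in range(n) if mask >> i & 1]
                if all(b - a >= 30 for a, b in zip(subset, subset[1:])):
                    best = max(best, len(subset))
            assert len(kept) == best

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            pdn.thin_by_distance([snv(100), snv(50)], 10)


class TestBudget:
    def test_required_bases(self):
        assert pdn.required_bases(1_000_000, 300, 15) == 4_500_000_000
        assert pdn.required_bases(0, 300, 15) == 0
        assert pdn.required_bases(2, 100, 10) == 2_000

    def test_genotypes_per_run(self):
        assert pdn.genotypes_per_run(3000, 326) == 978_000

    def test_max_panel_size_floor_division(self):
        assert pdn.max_panel_size(4.5e9, 300, 15, 326) == 3067
        assert pdn.max_panel_size(4.5e9, 300, 15, 1) == 1_000_000


class TestDesignPanel:
    def test_ledger_matches_planted_fixture(self, wild_fixture, reference_bundle):
        records, manifest = wild_fixture
        config = DesignConfig(subsample_fraction=1.0, rng_seed=0)
        panel = design_panel(
            records, reference_bundle.sequences, reference_bundle.repeats,
            config, placed_chrom_set={"chr1"},
        )
        per_stage = {}
        for info in manifest["variants"].values():
            if info["stage"]:
                per_stage[info["stage"]] = per_stage.get(info["stage"], 0) + 1
        for stage, expected in per_stage.items():
            assert panel.removed_at(stage) == expected, stage
        kept = {rec.locus_id() for rec in panel.loci}
        for locus, info in manifest["variants"].items():
            assert (locus in kept) == (info["vclass"] == "clean")

    def test_ledger_telescopes(self, wild_fixture, reference_bundle):
        records, _ = wild_fixture
        panel = design_panel(
            records, reference_bundle.sequences, reference_bundle.repeats,
            DesignConfig(subsample_fraction=0.5, rng_seed=1),
            placed_chrom_set={"chr1"},
        )
        for prev, nxt in zip(panel.ledger, panel.ledger[1:]):
            assert prev.n_out == nxt.n_in
        assert panel.ledger[-1].n_out == len(panel.loci)

    def test_spacing_invariant(self, wild_fixture, reference_bundle):
        records, _ = wild_fixture
        config = DesignConfig(subsample_fraction=1.0)
        panel = design_panel(
            records, reference_bundle.sequences, reference_bundle.repeats,
            config, placed_chrom_set={"chr1"},
        )
        by_chrom = {}
        for rec in panel.loci:
            by_chrom.setdefault(rec.chrom, []).append(rec.pos)
        for positions in by_chrom.values():
            assert all(b - a >= config.min_spacing
                       for a, b in zip(positions, positions[1:]))

    def test_monotonicity_in_thresholds(self, wild_fixture, reference_bundle):
        records, _ = wild_fixture
        base = DesignConfig(subsample_fraction=1.0)
        size = {}
        for name, cfg in {
            "base": base,
            "maf": DesignConfig(subsample_fraction=1.0, min_maf=0.3),
            "spacing": DesignConfig(subsample_fraction=1.0, min_spacing=60_000),
            "homopolymer": DesignConfig(subsample_fraction=1.0, homopolymer_min=8),
        }.items():
            size[name] = len(
                design_panel(records, reference_bundle.sequences,
                             reference_bundle.repeats, cfg,
                             placed_chrom_set={"chr1"}).loci
            )
        assert size["maf"] <= size["base"]
        assert size["spacing"] <= size["base"]
        assert size["homopolymer"] <= size["base"]

    def test_determinism(self, wild_fixture, reference_bundle, tmp_path):
        records, _ = wild_fixture
        cfg = DesignConfig(subsample_fraction=0.5, rng_seed=11)
        exports = []
        for name in ("a", "b"):
            panel = design_panel(records, reference_bundle.sequences,
                                 reference_bundle.repeats, cfg,
                                 placed_chrom_set={"chr1"})
            path = tmp_path / f"{name}.tsv"
            panel.write_tsv(str(path))
            exports.append(path.read_bytes())
        assert exports[0] == exports[1]

    def test_permissive_config_is_identity_modulo_indels(self, wild_fixture,
                                                         reference_bundle):
        records, _ = wild_fixture
        cfg = DesignConfig(
            repeat_flank=0, min_maf=0.0, max_mean_depth=math.inf,
            subsample_fraction=1.0, homopolymer_min=10**6,
            microsat_min_units=10**6, min_spacing=1,
        )
        panel = design_panel(records, reference_bundle.sequences, [], cfg,
                             placed_chrom_set={"chr1", "scaffold_1"})
        n_indels = sum(1 for r in records if not r.is_snv())
        assert len(panel.loci) == len(records) - n_indels

    def test_empty_panel_raises_with_ledger(self):
        records = [snv(100, genotypes=(0, 0, 0, 0))]  # MAF 0 -> filtered out
        with pytest.raises(ValueError, match="no loci") as excinfo:
            design_panel(records, {"chr1": "ACGT" * 1000}, [],
                         DesignConfig(subsample_fraction=1.0),
                         placed_chrom_set={"chr1"})
        assert hasattr(excinfo.value, "ledger")
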