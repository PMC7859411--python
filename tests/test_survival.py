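"""Marker assembly, mutual exclusivity, Cox PH fits, and paired comparisons."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from chordwgs import (
    CNProfile,
    GenomeBuild,
    SampleMetadata,
    Segment,
    SVRecord,
    VariantRecord,
    arm_scan,
    assemble_markers,
    bonferroni,
    fit_ph,
    km_curves,
    mutual_exclusivity,
    shared_fraction,
)
from chordwgs.scna import ArmEvent


@pytest.fixture(scope="module")
def genome():
    return GenomeBuild.hg19()


def diploid_profile(sid, genome):
    segs = [Segment(sid, c, s, e, 2, 1) for c, a, s, e in genome.arms()]
    return CNProfile(sid, segs)


def nonsyn(sid, gene, chrom, pos):
    return VariantRecord(
        sample_id=sid, chrom=chrom, pos=pos, ref="C", alt="T",
        t_alt=20, t_depth=80, n_alt=0, n_depth=40, n_callers=3,
        is_coding=True, is_nonsynonymous=True, gene=gene,
    )


class TestAssembleMarkers:
    def test_missense_sets_gene_flag(self, genome):
        profiles = [diploid_profile("S1", genome)]
        vs = [nonsyn("S1", "PBRM1", "chr3", 52_600_000)]
        markers = assemble_markers(vs, [], profiles, genome)
        assert bool(markers.loc["S1", "pbrm1_plus"])
        assert not markers.loc["S1", ["setd2_plus", "del22q"]].any()

    def test_homdel_over_cdkn2ab(self, genome):
        prof = diploid_profile("S1", genome)
        segs = [s for s in prof.segments if s.chrom != "chr9"]
        p_start, p_end = genome.arm_bounds["chr9"]["p"]
        segs += [
            Segment("S1", "chr9", p_start, 21_900_000, 2, 1),
            Segment("S1", "chr9", 21_900_000, 22_100_000, 0, 0),
            Segment("S1", "chr9", 22_100_000, p_end, 2, 1),
        ]
        markers = assemble_markers([], [], [CNProfile("S1", segs)], genome)
        assert bool(markers.loc["S1", "cdkn2ab_plus"])

    def test_sv_breakend_in_gene(self, genome):
        sv = SVRecord("S1", "chr3", 52_650_000, "+", "chr3", 60_000_000, "-")
        markers = assemble_markers([], [sv], [diploid_profile("S1", genome)], genome)
        assert bool(markers.loc["S1", "pbrm1_plus"])

    def test_combined_flags_are_exact_ors(self, genome, small_cohort):
        from chordwgs import apply_filters

        kept, _ = apply_filters(small_cohort.variants)
        markers = assemble_markers(kept, small_cohort.svs, small_cohort.profiles, genome)
        assert (markers["combined_css"] == (markers["pbrm1_plus"] | markers["del22q"])).all()
        assert (
            markers["combined_rfs"]
            == (markers["pbrm1_plus"] | markers["del9q21_focal"] | markers["del22q"])
        ).all()

    def test_idempotent_and_deterministic(self, genome):
        vs = [nonsyn("S1", "SETD2", "chr3", 47_100_000)]
        profiles = [diploid_profile("S1", genome), diploid_profile("S2", genome)]
        a = assemble_markers(vs, [], profiles, genome)
        b = assemble_markers(vs, [], profiles, genome)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_locus_raises(self, genome):
        with pytest.raises(KeyError, match="PBRM1"):
            assemble_markers([], [], [diploid_profile("S1", genome)], genome, loci={})


class TestMutualExclusivity:
    def test_disjoint_markers_hypergeometric_tail(self):
        a = np.array([1] * 2 + [0] * 18, dtype=bool)
        b = np.array([0] * 2 + [1] * 2 + [0] * 16, dtype=bool)
        overlap, p = mutual_exclusivity(a, b)
        assert overlap == 0
        # one-sided tail: P(X <= 0), X ~ Hypergeom(N=20, K=2, n=2)
        assert p == pytest.approx(float(hypergeom.cdf(0, 20, 2, 2)), rel=1e-9)

    def test_identical_markers_not_exclusive(self):
        a = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        overlap, p = mutual_exclusivity(a, a)
        assert overlap == 3 and p > 0.9

    def test_degenerate_all_false(self):
        overlap, p = mutual_exclusivity(np.zeros(10, bool), np.ones(10, bool))
        assert overlap == 0 and p == 1.0

    def test_independent_flags_calibrated(self):
        from scipy import stats

        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.random(60) < 0.3
            b = rng.random(60) < 0.3
            if a.sum() == 0 or b.sum() == 0:
                continue
            pvals.append(mutual_exclusivity(a, b)[1])
        # discrete conservative test: level should not exceed nominal
        assert np.mean(np.array(pvals) < 0.05) <= 0.05


def make_metadata(rng, n, marker, beta_rfs=0.0, h0=0.02):
    md = []
    for i in range(n):
        lp = beta_rfs * marker[i]
        t = rng.exponential(1 / (h0 * np.exp(lp)))
        c = rng.uniform(50, 300)
        md.append(
            SampleMetadata(
                sample_id=f"S{i}", age=float(rng.uniform(20, 70)),
                sex="M" if rng.random() < 0.5 else "F",
                pre_rt=bool(rng.random() < 0.2), post_rt=bool(rng.random() < 0.5),
                recurred=bool(t <= c), rfs_months=float(min(t, c)),
                died=False, os_months=1.0,
            )
        )
    return md


class TestFitPh:
    def test_matches_r_coxph_reference(self, tmp_path):
        """HR agrees with survival::coxph (Efron ties) to 1e-6 on a fixed
        50-row fixture."""
        rng = np.random.default_rng(123)
        n = 50
        df = pd.DataFrame(
            {
                "time": np.round(rng.exponential(30, n), 1) + 1,
                "event": (rng.random(n) < 0.7).astype(int),
                "age": np.round(rng.uniform(20, 70, n), 1),
                "sex_male": (rng.random(n) < 0.6).astype(int),
                "pre_rt": (rng.random(n) < 0.2).astype(int),
                "post_rt": (rng.random(n) < 0.5).astype(int),
                "marker": (rng.random(n) < 0.3).astype(int),
            }
        )
        df.loc[df.index[:10], "time"] = 12.0  # ties exercise Efron handling
        md = [
            SampleMetadata(
                sample_id=f"S{i}", age=row.age, sex="M" if row.sex_male else "F",
                pre_rt=bool(row.pre_rt), post_rt=bool(row.post_rt),
                recurred=bool(row.event), rfs_months=float(row.time),
                died=False, os_months=1.0,
            )
            for i, row in df.iterrows()
        ]
        marker = pd.Series(df["marker"].values.astype(bool),
                           index=[f"S{i}" for i in range(n)], name="marker")
        fit = fit_ph("rfs", marker, md)

        fixture = tmp_path / "cox.tsv"
        df.to_csv(fixture, sep="\t", index=False)
        rscript = textwrap.dedent(
            f"""
            library(survival)
            d <- read.delim("{fixture}")
            f <- coxph(Surv(time, event) ~ age + sex_male + pre_rt + post_rt + marker,
                       data = d, ties = "efron")
            cat(sprintf("%.12f", exp(coef(f))["marker"]))
            """
        )
        res = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        hr_r = float(res.stdout.strip())
        assert fit.hr == pytest.approx(hr_r, abs=1e-6)

    def test_effect_recovery(self):
        rng = np.random.default_rng(0)
        n = 400
        marker_arr = rng.random(n) < 0.3
        md = make_metadata(rng, n, marker_arr, beta_rfs=np.log(4.3))
        marker = pd.Series(marker_arr, index=[f"S{i}" for i in range(n)], name="m")
        fit = fit_ph("rfs", marker, md)
        assert fit.status == "ok"
        assert np.log(fit.hr) == pytest.approx(np.log(4.3), rel=0.2)
        assert fit.ci95[0] < fit.hr < fit.ci95[1]

    def test_constant_marker_no_fit(self):
        rng = np.random.default_rng(1)
        md = make_metadata(rng, 30, np.zeros(30, bool))
        marker = pd.Series(np.zeros(30, bool), index=[f"S{i}" for i in range(30)], name="m")
        fit = fit_ph("rfs", marker, md)
        assert fit.status == "no-fit" and "constant" in fit.reason

    def test_eventless_stratum_no_fit(self):
        rng = np.random.default_rng(2)
        marker_arr = np.array([True] * 5 + [False] * 25)
        md = make_metadata(rng, 30, marker_arr, h0=0.05)
        # kill all events in the marker-positive stratum
        for i in range(5):
            md[i] = SampleMetadata(
                sample_id=md[i].sample_id, age=md[i].age, sex=md[i].sex,
                pre_rt=md[i].pre_rt, post_rt=md[i].post_rt,
                recurred=False, rfs_months=md[i].rfs_months,
                died=False, os_months=1.0,
            )
        marker = pd.Series(marker_arr, index=[f"S{i}" for i in range(30)], name="m")
        fit = fit_ph("rfs", marker, md)
        assert fit.status == "no-fit" and "stratum" in fit.reason

    def test_km_curves_strata(self):
        rng = np.random.default_rng(3)
        marker_arr = rng.random(40) < 0.5
        md = make_metadata(rng, 40, marker_arr)
        marker = pd.Series(marker_arr, index=[f"S{i}" for i in range(40)], name="m")
        km = km_curves("rfs", marker, md)
        assert set(km["stratum"]) == {"negative", "positive"}
        assert ((km["survival"] >= 0) & (km["survival"] <= 1)).all()


class TestBonferroni:
    def test_printed_arithmetic(self):
        # 17 arm events at nominal p = 0.0027 -> corrected ~ 0.046
        assert bonferroni(0.0027, 17) == pytest.approx(0.0459)
        assert round(bonferroni(0.0027, 17), 3) == 0.046

    def test_capped_at_one(self):
        assert bonferroni(0.5, 17) == 1.0

    def test_single_test_identity(self):
        assert bonferroni(0.012, 1) == 0.012

    def test_arm_scan_applies_correction(self):
        rng = np.random.default_rng(4)
        marker_arr = rng.random(60) < 0.4
        md = make_metadata(rng, 60, marker_arr, beta_rfs=np.log(3.0))
        events = [
            ArmEvent(f"S{i}", "chr22", "q", "loss", 1.0)
            for i in np.flatnonzero(marker_arr)
        ]
        fits = arm_scan("rfs", events, md, m=17)
        (fit,) = fits
        assert fit.bonferroni_m == 17
        assert fit.p_adj == pytest.approx(min(1.0, 17 * fit.p))


class TestSharedFraction:
    def _pair_profiles(self):
        g = GenomeBuild(
            chrom_names=["chr1"], chrom_lengths={"chr1": 1000},
            arm_bounds={"chr1": {"p": (0, 500), "q": (500, 1000)}},
            autosome_flags={"chr1": True},
        )
        p = CNProfile("P", [Segment("P", "chr1", 0, 1000, 1, 0)])
        r = CNProfile("R", [Segment("R", "chr1", 0, 1000, 1, 0)])
        return p, r

    def test_identical_pairs_fully_shared(self):
        p, r = self._pair_profiles()
        vs = [nonsyn("P", "", "chr1", 5), nonsyn("R", "", "chr1", 5)]
        df = shared_fraction([("P", "R")], vs, [p, r])
        for _, row in df.iterrows():
            assert row["shared"] == 1.0
            assert row["primary_only"] == 0.0 and row["recurrence_only"] == 0.0

    def test_disjoint_snv_sets(self):
        p, r = self._pair_profiles()
        vs = [nonsyn("P", "", "chr1", 5), nonsyn("R", "", "chr1", 9)]
        df = shared_fraction([("P", "R")], vs, [p, r])
        snv = df[df["class"] == "snv"].iloc[0]
        assert snv["shared"] == 0.0
        assert snv["primary_only"] == 0.5 and snv["recurrence_only"] == 0.5

    def test_three_of_four_shared_union_convention(self):
        p, r = self._pair_profiles()
        shared_pos = [10, 20, 30]
        vs = [nonsyn("P", "", "chr1", q) for q in shared_pos + [40]]
        vs += [nonsyn("R", "", "chr1", q) for q in shared_pos]
        df = shared_fraction([("P", "R")], vs, [p, r])
        snv = df[df["class"] == "snv"].iloc[0]
        assert snv["shared"] == pytest.approx(0.75)

    def test_proportions_sum_to_one(self, small_cohort):
        ids = [p.sample_id for p in small_cohort.profiles[:6]]
        pairs = list(zip(ids[0::2], ids[1::2]))
        df = shared_fraction(pairs, small_cohort.variants, small_cohort.profiles)
        sums = df[["shared", "primary_only", "recurrence_only"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_unpaired_sample_skipped_with_warning(self, caplog):
        p, _ = self._pair_profiles()
        with caplog.at_level("WARNING", logger="chordwgs"):
            df = shared_fraction([("P", "MISSING")], [], [p])
        assert df.empty and "skipped" in caplog.text
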