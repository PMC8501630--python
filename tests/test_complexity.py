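"""Eight-index complexity scoring: worked examples, invariants, oracle parity."""

import math

import numpy as np
import pytest

from ascopy import (
    SCORE_NAMES,
    GenomeLayout,
    ScoreConfig,
    score_arm_wise,
    score_genome_wide,
    score_region,
)

from conftest import make_profile
from oracles import per_base_scores, random_small_profile

MB = 1_000_000


def scores_of(segs, ploidy, w0=3 * MB, region=None):
    profile = make_profile(segs)
    return score_region(profile, region, ploidy, ScoreConfig(w0=w0), region_id="r")


class TestWorkedExamples:
    def test_flat_balanced_diploid_is_all_zero(self):
        s = scores_of([("1", 1, 100 * MB, 1, 1)], ploidy=2.0)
        assert all(v == 0 for v in s.as_dict().values())

    def test_focal_gain_on_balanced_arm(self):
        # 100 Mb arm: (1,1) x 45 Mb, (2,1) x 10 Mb, (1,1) x 45 Mb; P = 2, w0 = 3 Mb
        s = scores_of(
            [
                ("1", 1, 45 * MB, 1, 1),
                ("1", 45 * MB + 1, 55 * MB, 2, 1),
                ("1", 55 * MB + 1, 100 * MB, 1, 1),
            ],
            ploidy=2.0,
        )
        expected = {
            "var": 0.1, "steep": 0.06, "curv": 0.03, "dev": 0.1,
            "gain": 0.1, "loss": 0.0, "loh": 0.0, "asym": 0.1,
        }
        for name, value in expected.items():
            assert getattr(s, name) == pytest.approx(value), name

    def test_copy_neutral_loh(self):
        # (1,1) x 80 Mb then (2,0) x 20 Mb: copy-neutral, only loh fires
        s = scores_of(
            [("1", 1, 80 * MB, 1, 1), ("1", 80 * MB + 1, 100 * MB, 2, 0)],
            ploidy=2.0,
        )
        assert s.loh == pytest.approx(0.4)
        for name in ("var", "steep", "curv", "dev", "gain", "loss", "asym"):
            assert getattr(s, name) == 0, name

    def test_homozygous_deletion_feeds_loss_not_loh(self):
        s = scores_of(
            [("1", 1, 90 * MB, 1, 1), ("1", 90 * MB + 1, 100 * MB, 0, 0)],
            ploidy=2.0,
        )
        assert s.loh == 0
        assert s.loss == pytest.approx(0.2)

    def test_zero_coverage_region_is_missing_not_zero(self):
        profile = make_profile([("1", 1, MB, 1, 1)])
        s = score_region(profile, [("2", 1, MB)], 2.0)
        assert all(math.isnan(v) for v in s.as_dict().values())


class TestGenomeWide:
    def test_exactly_eight_scores(self, flat_diploid):
        s = score_genome_wide(flat_diploid)
        assert len(s.as_dict()) == 8 and s.region == "genome"

    def test_deterministic(self, demo_cohort):
        p = demo_cohort.profiles[0]
        assert score_genome_wide(p) == score_genome_wide(p)

    def test_scale_invariance_with_coscaled_cap(self, rng):
        segs = random_small_profile(rng)
        scaled = [(c, (s - 1) * 10 + 1, e * 10, a, b) for c, s, e, a, b in segs]
        base = scores_of(segs, ploidy=2.0, w0=50)
        big = scores_of(scaled, ploidy=2.0, w0=500)
        for name in SCORE_NAMES:
            assert getattr(big, name) == pytest.approx(getattr(base, name)), name

    def test_uncapped_scores_invariant_under_pure_length_scaling(self, rng):
        segs = random_small_profile(rng)
        scaled = [(c, (s - 1) * 10 + 1, e * 10, a, b) for c, s, e, a, b in segs]
        base = scores_of(segs, ploidy=2.0, w0=3 * MB)
        big = scores_of(scaled, ploidy=2.0, w0=3 * MB)
        for name in ("var", "dev", "gain", "loss", "loh", "asym"):
            assert getattr(big, name) == pytest.approx(getattr(base, name)), name

    def test_split_segment_invariance(self):
        segs = [("1", 1, 40 * MB, 2, 1), ("1", 40 * MB + 1, 100 * MB, 1, 1)]
        split = [
            ("1", 1, 20 * MB, 2, 1),
            ("1", 20 * MB + 1, 40 * MB, 2, 1),
            ("1", 40 * MB + 1, 100 * MB, 1, 1),
        ]
        a, b = scores_of(segs, 2.0), scores_of(split, 2.0)
        assert a.as_dict() == pytest.approx(b.as_dict())


class TestOracleEquivalence:
    def test_matches_per_base_oracle_on_random_profiles(self, rng):
        """All eight scores agree with brute-force per-base evaluation."""
        for i in range(50):
            segs = random_small_profile(rng)
            ploidy = float(rng.uniform(1.0, 4.0))
            w0 = float(rng.integers(5, 500))
            ours = scores_of(segs, ploidy, w0=w0).as_dict()
            ref = per_base_scores(segs, ploidy, w0=w0)
            for name in SCORE_NAMES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-12), (i, name)

    def test_dev_decomposes_into_gain_plus_loss(self, rng):
        for _ in range(30):
            segs = random_small_profile(rng)
            s = scores_of(segs, float(rng.uniform(1.0, 4.0)))
            assert s.dev == pytest.approx(s.gain + s.loss)


class TestArmWise:
    def test_default_layout_gives_344_values(self, layout, flat_diploid):
        scores = score_arm_wise(flat_diploid, layout)
        assert len(scores) == 43
        assert sum(len(s.as_dict()) for s in scores) == 344

    def test_locality_of_arm_aberration(self, layout):
        arm_1q = next(a for a in layout.arms if a.name == "1q")
        segs = []
        for arm in layout.arms:
            if arm.name == "1q":
                mid = (arm.start + arm.end) // 2
                segs.append((arm.chrom, arm.start, mid, 2, 1))
                segs.append((arm.chrom, mid + 1, arm.end, 1, 1))
            else:
                segs.append((arm.chrom, arm.start, arm.end, 1, 1))
        profile = make_profile(segs)
        for s in score_arm_wise(profile, layout):
            if s.region == "1q":
                assert s.gain > 0 and s.steep > 0
            else:
                for name in ("var", "steep", "curv", "gain", "loss", "loh", "asym"):
                    assert getattr(s, name) == 0, (s.region, name)

    def test_uncovered_arms_flagged_missing(self, layout):
        segs = [
            (arm.chrom, arm.start, arm.end, 1, 1)
            for arm in layout.arms if arm.chrom != "Y"
        ]
        profile = make_profile(segs)
        scores = score_arm_wise(profile, layout)
        missing = {s.region for s in scores if s.missing}
        assert missing == {"Yp", "Yq"}
        assert sum(not s.missing for s in scores) == 41

    def test_focal_complex_raises_steep_and_curv(self, layout):
        """Oscillating short segments increase J2/J3; an arm gain does not."""
        def arm_profile(aberrant):
            segs = []
            for arm in layout.arms:
                if arm.name == "2p" and aberrant == "complex":
                    pos = arm.start
                    for j in range(5):
                        end = pos + 400_000 - 1
                        a = 2 if j % 2 else 1
                        segs.append((arm.chrom, pos, end, a, 1))
                        pos = end + 1
                    segs.append((arm.chrom, pos, arm.end, 1, 1))
                elif arm.name == "2p" and aberrant == "arm_gain":
                    segs.append((arm.chrom, arm.start, arm.end, 2, 1))
                else:
                    segs.append((arm.chrom, arm.start, arm.end, 1, 1))
            return make_profile(segs, ploidy=2.0)

        flat = {s.region: s for s in score_arm_wise(arm_profile("none"), layout)}
        osc = {s.region: s for s in score_arm_wise(arm_profile("complex"), layout)}
        gained = {s.region: s for s in score_arm_wise(arm_profile("arm_gain"), layout)}
        assert osc["2p"].steep > flat["2p"].steep
        assert osc["2p"].curv > flat["2p"].curv
        assert gained["2p"].gain > flat["2p"].gain
        assert gained["2p"].dev > flat["2p"].dev
        assert gained["2p"].curv == flat["2p"].curv == 0
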