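import warnings
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaprs import (
    DosageMatrix,
    QCThresholds,
    SimConfig,
    compute_pcs,
    hwe_exact_p,
    pihat_matrix,
    platform_harmonize,
    sample_qc,
    simulate_genotypes,
    variant_qc,
)
from metaprs.exceptions import EmptyPanelError, InvalidConfigError
from metaprs.qc import PRESETS


def hwe_oracle(n_aa, n_ab, n_bb):
    """Brute-force exact-rational enumeration over heterozygote counts."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)

    def prob(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        # multinomial table count x 2^h, over C(2n, rare) allele arrangements
        num = Fraction(
            comb(n, hr) * comb(n - hr, h) * 2**h, comb(2 * n, rare)
        )
        return num

    if rare == 0:
        return 1.0
    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    p = sum(v / total for v in probs.values() if v / total <= p_obs)
    return float(p)


class TestHWE:
    def test_single_table(self):
        assert hwe_exact_p(0, 0, 50) == 1.0

    def test_modal_table(self):
        # full enumeration: the observed table is modal, all tables count
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_small_table_vs_oracle(self):
        assert hwe_exact_p(3, 1, 5) == pytest.approx(hwe_oracle(3, 1, 5), abs=1e-12)

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)

    def test_empty_table(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    @settings(max_examples=150, deadline=None)
    @given(
        n_aa=st.integers(0, 70),
        n_ab=st.integers(0, 70),
        n_bb=st.integers(0, 60),
    )
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_p(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_oracle(n_aa, n_ab, n_bb), abs=1e-12
        )


def _panel(dosages, refs=None, alts=None, chroms=None, poss=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chroms or ["1"] * m,
            "pos": poss or list(range(100, 100 + m)),
            "ref": refs or ["A"] * m,
            "alt": alts or ["G"] * m,
        }
    )
    return DosageMatrix(dosages, variants)


class TestVariantQC:
    def test_call_rate_failure(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0, 0, 1, 2, 1, 0, 1], (3, 1)).T  # 10 x 3
        d[:, 0] = [np.nan, 1, 2, 1, 0, 1, 2, 1, 0, 1]  # 10% missing
        dm = _panel(d)
        _, report = variant_qc(dm, QCThresholds(variant_call_rate_min=0.95))
        assert report.variants.loc[0, "reason"] == "call_rate"

    def test_maf_failure(self):
        d = np.full((200, 2), 2.0)
        d[0, 0] = 0.0  # MAF 0.005 in column 0
        d[:100, 1] = 1.0  # common variant passes
        dm = _panel(d)
        _, report = variant_qc(dm, QCThresholds(maf_min=0.01, hwe_p_min=1e-30))
        assert report.variants.loc[0, "reason"] == "maf"
        assert bool(report.variants.loc[1, "pass"])

    def test_monomorphic_removed_by_maf_not_hwe(self):
        d = np.zeros((50, 2))
        d[:25, 1] = 1.0
        dm = _panel(d)
        _, report = variant_qc(dm, QCThresholds())
        assert report.variants.loc[0, "reason"] == "maf"
        assert report.variants.loc[0, "hwe_p"] == 1.0

    def test_hwe_failure(self):
        # all heterozygous: strong HWE violation
        het = np.ones((100, 1))
        ok = np.random.default_rng(0).binomial(2, 0.3, size=(100, 1)).astype(float)
        dm = _panel(np.hstack([het, ok]))
        _, report = variant_qc(dm, QCThresholds(hwe_p_min=1e-5))
        assert report.variants.loc[0, "reason"] == "hwe"

    def test_ambiguous_and_multiallelic(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        dm = _panel(d, refs=["A", "A", "A"], alts=["T", "G", "G,C"])
        _, report = variant_qc(dm, QCThresholds())
        assert report.variants.loc[0, "reason"] == "ambiguous_strand"
        assert report.variants.loc[2, "reason"] == "multi_allelic"

    def test_empty_panel_error(self):
        dm = _panel(np.zeros((50, 1)))  # monomorphic -> removed
        with pytest.raises(EmptyPanelError):
            variant_qc(dm, QCThresholds())

    def test_idempotent(self):
        cfg = SimConfig(
            n_individuals=300, n_variants=150, seed=20,
            missing_rate=0.03, ambiguous_fraction=0.1, maf_range=(0.005, 0.5),
        )
        dm = simulate_genotypes(cfg)
        once, _ = variant_qc(dm, PRESETS["cnics"])
        twice, report = variant_qc(once, PRESETS["cnics"])
        assert report.n_variants_removed == 0
        assert twice.n_variants == once.n_variants

    def test_exactly_one_reason(self):
        cfg = SimConfig(
            n_individuals=200, n_variants=100, seed=21,
            missing_rate=0.04, ambiguous_fraction=0.1, maf_range=(0.005, 0.5),
        )
        _, report = variant_qc(simulate_genotypes(cfg), PRESETS["cnics"])
        removed = report.variants[~report.variants["pass"]]
        assert (removed["reason"] != "").all()
        kept = report.variants[report.variants["pass"]]
        assert (kept["reason"] == "").all()

    def test_presets_match_thresholds(self):
        cnics = PRESETS["cnics"]
        assert (cnics.variant_call_rate_min, cnics.maf_min) == (0.95, 0.01)
        assert cnics.hwe_p_min == 1e-05
        assert cnics.sample_call_rate_min == 0.90
        assert cnics.pihat_max == 0.9
        assert cnics.platform_p_remove == 5e-08
        assert PRESETS["regards1"].variant_call_rate_min == 0.90
        assert PRESETS["regards1"].hwe_p_min == 1e-12


class TestSampleQC:
    def test_duplicate_sample_removed(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(30, 200)).astype(float)
        d[1] = d[0]  # duplicate pair (0, 1)
        dm = _panel(d)
        ph = pihat_matrix(dm)
        assert ph[0, 1] == pytest.approx(1.0, abs=1e-9)
        kept, report = sample_qc(dm, QCThresholds(pihat_max=0.9))
        # equal call rates: later index removed
        assert report.samples.loc[1, "reason"] == "pihat"
        assert bool(report.samples.loc[0, "pass"])

    def test_unrelated_pihat_near_zero(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.5, 500)
        d = rng.binomial(2, p, size=(20, 500)).astype(float)
        ph = pihat_matrix(_panel(d))
        off = ph[np.triu_indices(20, k=1)]
        assert np.all(np.abs(off) < 0.1)

    def test_no_removals_with_loose_threshold(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, size=(15, 100)).astype(float)
        _, report = sample_qc(_panel(d), QCThresholds(pihat_max=1.1))
        assert report.n_samples_removed == 0

    def test_call_rate_removal(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.3, size=(10, 100)).astype(float)
        d[0, :20] = np.nan  # 80% call rate
        _, report = sample_qc(_panel(d), QCThresholds(sample_call_rate_min=0.9))
        assert report.samples.loc[0, "reason"] == "call_rate"


class TestPCs:
    def test_population_structure_on_pc1(self):
        cfg = SimConfig(
            n_individuals=300, n_variants=400, seed=22,
            n_ancestries=2, ancestry_freq_shift=0.3,
        )
        dm = simulate_genotypes(cfg)
        ancestry = dm.variants.attrs["ancestry"]
        pcs = compute_pcs(dm, 5)
        g0, g1 = pcs[ancestry == 0, 0], pcs[ancestry == 1, 0]
        assert np.sign(g0.mean()) != np.sign(g1.mean())
        within = max(g0.std(), g1.std())
        assert abs(g0.mean() - g1.mean()) > 4 * within

    def test_orthogonality_and_order(self):
        dm = simulate_genotypes(SimConfig(n_individuals=100, n_variants=200, seed=23))
        d = dm.dosages
        p = d.mean(axis=0) / 2
        x = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
        s = np.linalg.svd(x, compute_uv=False)
        assert np.all(np.diff(s) <= 1e-9)
        pcs = compute_pcs(dm, 8)
        gram = pcs.T @ pcs
        assert np.allclose(gram, np.eye(8), atol=1e-8)

    def test_npcs_bound(self):
        dm = simulate_genotypes(SimConfig(n_individuals=20, n_variants=30, seed=24))
        with pytest.raises(InvalidConfigError):
            compute_pcs(dm, 20)

    def test_zero_variance_warning(self):
        d = np.random.default_rng(6).binomial(2, 0.3, (50, 5)).astype(float)
        d[:, 2] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            compute_pcs(_panel(d), 2)


class TestPlatformHarmonize:
    def _pcs(self, n):
        return np.zeros((n, 2))

    def test_single_platform_noop(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.3, (60, 20)).astype(float)
        dm = _panel(d)
        with pytest.warns(UserWarning, match="single platform"):
            out, _ = platform_harmonize(dm, np.zeros(60), self._pcs(60))
        np.testing.assert_array_equal(out.dosages, dm.dosages)

    def test_null_variants_not_removed(self):
        rng = np.random.default_rng(8)
        n, m = 600, 1000
        d = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        platform = rng.integers(0, 2, n)
        out, report = platform_harmonize(_panel(d), platform, self._pcs(n), 5e-8)
        assert report.n_variants_removed <= 2

    def test_injected_shift_removed(self):
        rng = np.random.default_rng(9)
        n = 4000
        platform = np.repeat([0, 1], n // 2)
        d = rng.binomial(2, 0.1, size=(n, 10)).astype(float)
        d[platform == 0, 0] = rng.binomial(2, 0.5, n // 2)  # 0.1 -> 0.5 shift
        out, report = platform_harmonize(_panel(d), platform, self._pcs(n), 5e-8)
        assert report.variants.loc[0, "reason"] == "platform_association"
        assert report.n_variants_removed == 1

    def test_three_platform_merge(self):
        rng = np.random.default_rng(10)
        n = 1500
        platform = np.repeat([0, 1, 2], n // 3)
        d = rng.binomial(2, 0.3, size=(n, 8)).astype(float)
        # variant 0 shifted only on platform 2: caught in the second merge
        d[platform == 2, 0] = rng.binomial(2, 0.8, n // 3)
        out, report = platform_harmonize(_panel(d), platform, self._pcs(n), 5e-8)
        assert not bool(report.variants.loc[0, "pass"])
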