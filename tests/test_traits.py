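"""Trait derivation, collinearity pruning, standardisation, per-trait ANOVA."""

import numpy as np
import pandas as pd
import pytest

from cytotraits.gating import EventTable, GatedPopulation
from cytotraits.traits import (
    TRAIT_NAMES, TraitMatrix, StandardizationModel,
    derive_traits, collinearity_filter, standardize, unstandardize,
    anova_per_trait,
)

CH = ["FSC", "SSC", "FL670", "FL692"]


def _gated(rows):
    vals = np.asarray(rows, float)
    table = EventTable("s", CH, vals)
    return GatedPopulation(table, np.arange(len(vals)), np.zeros(len(vals), int))


class TestDeriveTraits:
    def test_arithmetic_closed_form(self):
        tm = derive_traits(_gated([[100, 50, 200, 100]]), volume_exponent=1.0)
        row = dict(zip(tm.trait_names, tm.values[0]))
        assert row["cell_size"] == 100
        assert row["granularity"] == 50
        assert row["gas_vesicle"] == 2.0
        assert row["phycocyanin"] == 200
        assert row["chlorophyll_a"] == 100
        assert row["pc_per_size"] == 2.0
        assert row["chla_per_size"] == 1.0
        assert row["pc_chla"] == 2.0

    def test_volume_exponent(self):
        tm = derive_traits(_gated([[100, 50, 200, 100]]), volume_exponent=1.5)
        assert dict(zip(tm.trait_names, tm.values[0]))["gas_vesicle"] == pytest.approx(20.0)

    def test_zero_denominator_dropped_and_counted(self):
        tm = derive_traits(_gated([[100, 0, 200, 100], [100, 50, 200, 100]]))
        assert tm.n_events == 1
        assert tm.n_dropped == 1

    def test_trait_names_and_order(self):
        tm = derive_traits(_gated([[1, 1, 1, 1]]))
        assert tm.trait_names == TRAIT_NAMES

    def test_pigment_scale_consistency(self, rng):
        """Scaling both pigment channels by c leaves the PC:Chl-a ratio unchanged."""
        vals = rng.uniform(10, 1000, size=(50, 4))
        scaled = vals.copy()
        scaled[:, 2:] *= 7.3
        a = derive_traits(_gated(vals))
        b = derive_traits(_gated(scaled))
        k = TRAIT_NAMES.index("pc_chla")
        np.testing.assert_allclose(a.values[:, k], b.values[:, k], rtol=1e-12)


class TestCollinearityFilter:
    def test_perfect_pair_drops_one(self, rng):
        x = rng.uniform(1, 100, 200)
        df = pd.DataFrame({"a": x, "b": x * 3.0, "c": rng.uniform(1, 100, 200)})
        kept = collinearity_filter(df, r_threshold=0.8)
        assert "c" in kept
        assert len([k for k in kept if k in ("a", "b")]) == 1

    def test_keep_list_protects_pigments(self, rng):
        z = rng.standard_normal(500)
        fl670 = np.exp(z + 0.3 * rng.standard_normal(500))
        fl692 = np.exp(z + 0.3 * rng.standard_normal(500))  # r ~ 0.9 on log scale
        df = pd.DataFrame({"FL670": fl670, "FL692": fl692})
        kept = collinearity_filter(df, r_threshold=0.8, keep_list=["FL670", "FL692"])
        assert set(kept) == {"FL670", "FL692"}

    def test_uncorrelated_all_retained(self, rng):
        df = pd.DataFrame(np.exp(rng.standard_normal((300, 5))),
                          columns=list("abcde"))
        assert collinearity_filter(df, r_threshold=0.8) == list("abcde")

    def test_missing_keep_entry_rejected(self, rng):
        df = pd.DataFrame(np.exp(rng.standard_normal((50, 2))), columns=["a", "b"])
        with pytest.raises(ValueError, match="keep_list"):
            collinearity_filter(df, keep_list=["zz"])


class TestStandardize:
    def _tm(self, vals):
        return TraitMatrix("s", [f"t{i}" for i in range(vals.shape[1])], vals)

    def test_fit_gives_zero_mean_unit_sd(self, rng):
        tm = self._tm(rng.uniform(1, 100, size=(200, 3)))
        z, model = standardize(tm)
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=0), 1, atol=1e-8)
        assert z.standardized

    def test_constant_trait_rejected(self):
        vals = np.column_stack([np.full(20, 5.0), np.arange(1.0, 21.0)])
        with pytest.raises(ValueError, match="constant"):
            standardize(self._tm(vals))

    def test_transport_of_shifted_copy_closed_form(self, rng):
        """Applying a fitted model to data scaled by 10 shifts each column
        mean by exactly 1/sd on the log10 scale."""
        vals = rng.uniform(1, 100, size=(500, 2))
        base = self._tm(vals)
        _, model = standardize(base)
        shifted, _ = standardize(self._tm(vals * 10.0), model)
        expected = shifted.values.mean(axis=0)
        base_z, _ = standardize(self._tm(vals), model)
        np.testing.assert_allclose(
            expected, base_z.values.mean(axis=0) + 1.0 / model.sd, atol=1e-9
        )

    def test_roundtrip_restores_values(self, rng):
        tm = self._tm(rng.uniform(1, 100, size=(100, 3)))
        z, model = standardize(tm)
        back = unstandardize(z, model)
        np.testing.assert_allclose(back.values, tm.values, rtol=1e-9)

    def test_model_sd_must_be_positive(self):
        with pytest.raises(ValueError, match="sd must be > 0"):
            StandardizationModel(["a"], np.array([0.0]), np.array([0.0]))


class TestAnova:
    def _groups(self, arrays, names=None):
        out = []
        for i, arr in enumerate(arrays):
            tm = TraitMatrix("s%d" % i, ["t0"], np.asarray(arr, float).reshape(-1, 1),
                             standardized=True)
            tm.treatment = (names or [f"g{i}" for i in range(len(arrays))])[i]
            out.append(tm)
        return out

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(30) + 0.5
        from scipy import stats
        res = anova_per_trait(self._groups([a, b]))
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res["F"][0] == pytest.approx(t.statistic ** 2, rel=1e-10)

    def test_matches_brute_force_sums_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]
        res = anova_per_trait(self._groups(groups))
        # brute force: SSB/(k-1) / (SSW/(N-k))
        flat = np.concatenate(groups)
        grand = flat.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        F = (ssb / 1) / (ssw / 4)
        assert res["F"][0] == pytest.approx(F, rel=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            anova_per_trait(self._groups([[1.0, 2.0]]))
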