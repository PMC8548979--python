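"""Robust correlation, Fisher Z, subject matrices, group edge maps."""

import numpy as np
import pytest

from nirspain.connectivity import (
    ConnectivityMatrix,
    canonical_pairs,
    fisher_z,
    group_edges,
    robust_correlation,
    subject_connectivity,
)
from nirspain.preprocess import HemoglobinTimeSeries


def _hb(data, rate=4.0):
    data = np.atleast_2d(data)
    return HemoglobinTimeSeries(
        hbo=data, hbr=-data / 3.0, sampling_rate=rate
    )


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_value(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)

    def test_antisymmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, 20)
        assert np.allclose(fisher_z(-r), -np.asarray(fisher_z(r)))

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_unit_correlation_rejected(self, bad):
        with pytest.raises(ValueError, match="< 1"):
            fisher_z(bad)


class TestRobustCorrelation:
    def test_identity_gives_one(self, rng):
        x = rng.standard_normal(200)
        assert robust_correlation(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_plain_flag_matches_pearson(self, rng):
        x = rng.standard_normal(300)
        y = 0.4 * x + rng.standard_normal(300)
        r = robust_correlation(x, y, robust=False, prewhiten=False)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            robust_correlation(np.ones(100), rng.standard_normal(100))

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="30"):
            robust_correlation(rng.standard_normal(10),
                               rng.standard_normal(10))

    def test_null_distribution_centred(self, rng):
        rs = [
            robust_correlation(rng.standard_normal(300),
                               rng.standard_normal(300))
            for _ in range(200)
        ]
        assert abs(np.mean(rs)) < 0.02
        assert np.std(rs) == pytest.approx(1 / np.sqrt(300), rel=0.25)

    def test_outlier_resistance(self, rng):
        """5% gross outliers: robust r stays near truth, Pearson drifts."""
        n = 1000
        target = 0.6
        err_rob, err_plain = [], []
        for _ in range(10):
            f = rng.standard_normal(n)
            x = np.sqrt(target) * f + np.sqrt(1 - target) * \
                rng.standard_normal(n)
            y = np.sqrt(target) * f + np.sqrt(1 - target) * \
                rng.standard_normal(n)
            idx = rng.choice(n, n // 20, replace=False)
            x_c = x.copy()
            x_c[idx] += rng.choice([-10, 10], len(idx))
            err_rob.append(abs(
                robust_correlation(x_c, y, prewhiten=False) - target
            ))
            err_plain.append(abs(np.corrcoef(x_c, y)[0, 1] - target))
        assert np.mean(err_rob) < 0.1
        assert np.mean(err_rob) < np.mean(err_plain)


class TestSubjectConnectivity:
    def test_permutation_equivariance(self, rng):
        data = rng.standard_normal((6, 400))
        data[1] += data[0]  # correlated pair
        m = subject_connectivity(_hb(data), band="low", prefiltered=True,
                                 prewhiten=False)
        perm = rng.permutation(6)
        m_p = subject_connectivity(_hb(data[perm]), band="low",
                                   prefiltered=True, prewhiten=False)
        assert np.allclose(
            m.z[np.ix_(perm, perm)], m_p.z, equal_nan=True, atol=1e-10
        )

    def test_duplicated_channel_masked_with_warning(self, rng):
        data = rng.standard_normal((4, 300))
        data[3] = data[2]
        with pytest.warns(RuntimeWarning, match="degenerate"):
            m = subject_connectivity(_hb(data), band="low", prefiltered=True,
                                     prewhiten=False)
        assert np.isnan(m.z[2, 3])
        assert np.isfinite(m.z[0, 1])

    def test_symmetry_and_masked_diagonal(self, rng):
        data = rng.standard_normal((5, 300))
        m = subject_connectivity(_hb(data), band="low", prefiltered=True)
        assert np.allclose(m.z, m.z.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(m.z)))

    def test_planted_edge_is_matrix_maximum(self, tiny_cfg):
        """With 300 s of breathing data the planted edges dominate the map."""
        from nirspain.preprocess import (
            intensity_to_od,
            od_to_hemoglobin,
            resample,
        )
        from nirspain.simulate import simulate_subject, simulate_tqst_events

        cfg = tiny_cfg.with_(breathing_s=300.0, rest_pre_s=10.0, seed=7)
        events = simulate_tqst_events(
            np.full(2, 40.0), start_s=cfg.rest_pre_s + cfg.breathing_s
        )
        phases = {
            "breathing": (cfg.rest_pre_s, cfg.rest_pre_s + cfg.breathing_s),
            "tqst": (cfg.rest_pre_s + cfg.breathing_s,
                     events.end_time() + 10.0),
        }
        target_z = np.array([np.arctanh(r) for _, _, r in cfg.edge_set])
        rec, _ = simulate_subject(cfg, events, 13, phases=phases,
                                  edge_z=target_z)
        hb = resample(
            od_to_hemoglobin(intensity_to_od(rec)).crop(*phases["breathing"]),
            4.0,
        )
        m = subject_connectivity(hb, band="low", subject="s")
        z = np.abs(np.where(np.isnan(m.z), 0.0, m.z))
        flat_max = np.unravel_index(np.argmax(z), z.shape)
        planted = {
            tuple(sorted((a - 1, b - 1))) for a, b, _ in cfg.edge_set
        }
        assert tuple(sorted(flat_max)) in planted


class TestGroupEdges:
    def _mat(self, z, subject, visit=1):
        return ConnectivityMatrix(subject=subject, band="low", z=z,
                                  visit=visit)

    def test_identical_matrices_recovered_exactly(self, rng):
        base = rng.standard_normal((6, 6))
        z = (base + base.T) / 2
        np.fill_diagonal(z, np.nan)
        res = group_edges([self._mat(z, f"s{i}") for i in range(5)])
        ia, ib = np.triu_indices(6, 1)
        assert np.allclose(res.mean_z, z[ia, ib])
        nonzero = z[ia, ib] != 0
        assert np.all(res.pvalues[nonzero] < 1e-12)

    def test_two_subjects_rejected(self, rng):
        z = np.zeros((4, 4))
        mats = [self._mat(z, "a"), self._mat(z, "b")]
        with pytest.raises(ValueError, match="3 subjects"):
            group_edges(mats)

    def test_mixed_bands_rejected(self, rng):
        z = np.zeros((4, 4))
        mats = [
            ConnectivityMatrix(subject=s, band=b, z=z)
            for s, b in [("a", "low"), ("b", "high"), ("c", "low")]
        ]
        with pytest.raises(ValueError, match="bands"):
            group_edges(mats)

    def test_planted_group_structure_recovered(self, rng):
        """Edges with a planted mean Z reach p<.001; nulls survive FDR."""
        n_ch, n_sub = 10, 16
        pairs = canonical_pairs(n_ch)
        planted = [(1, 2), (3, 7)]
        mats = []
        for i in range(n_sub):
            z = rng.standard_normal((n_ch, n_ch)) * 0.1
            z = (z + z.T) / 2
            for a, b in planted:
                z[a - 1, b - 1] = z[b - 1, a - 1] = 0.7 + \
                    0.2 * rng.standard_normal()
            np.fill_diagonal(z, np.nan)
            mats.append(self._mat(z, f"s{i}"))
        res = group_edges(mats)
        sig = {tuple(p) for p in res.significant_pairs()}
        assert sig == set(planted)
        null_mask = np.array(
            [tuple(p) not in set(planted) for p in map(tuple, res.pairs)]
        )
        assert not (res.qvalues[null_mask] < 0.05).any()

    def test_canonical_pair_count(self):
        assert len(canonical_pairs(45)) == 990
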