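"""Spherical forward model, eLORETA inverse and ROI extraction."""

import numpy as np
import pytest
import scipy.linalg

import envconn as ec
from envconn import inverse as inv
from envconn import simulate as sim
from envconn.preprocess import filter_and_rereference


class TestForwardModel:
    def test_series_matches_closed_form_infinite_medium(self):
        """The multipole expansion must reduce to q.(r-r0)/(4 pi s |r-r0|^3).

        With equal shell conductivities and the field point well inside the
        outer boundary the scalp-response correction is small but exact; we
        instead exploit the homogeneous-sphere solution: for a central
        dipole only the n=1 term survives and V = 3 q cos(theta)/(4 pi s R^2).
        """
        sens = sim.synthetic_montage(24)[1]
        pots = inv.dipole_potentials(
            np.zeros(3), sens, radii=(80.0, 85.0, 92.0),
            conductivities=(0.33, 0.33, 0.33),
        )
        fitted = inv.fit_sensors_to_scalp(sens, 92.0)
        cos_t = fitted[:, 2] / 92.0
        expected = (
            3.0 * cos_t * 1e-9 / (4 * np.pi * 0.33 * 0.092**2) * 1e6
        )
        assert np.allclose(pots[:, 2], expected, rtol=1e-10)
        # x/y dipoles at the centre follow the same law along their axes
        assert np.allclose(pots[:, 0], expected * fitted[:, 0] / (92.0 * cos_t))

    def test_central_dipole_pattern_proportional_to_cos_polar_angle(self):
        sens = sim.synthetic_montage(20)[1]
        pots = inv.dipole_potentials(np.zeros(3), sens)
        cos_t = inv.fit_sensors_to_scalp(sens, 92.0)[:, 2] / 92.0
        ratio = pots[:, 2] / cos_t
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_potentials_linear_in_moment(self):
        sens = sim.synthetic_montage(20)[1]
        pots = inv.dipole_potentials(np.array([10.0, -20.0, 30.0]), sens)
        q = np.array([1.0, 2.0, -0.5])
        assert np.allclose(pots @ (3.0 * q), 3.0 * (pots @ q), rtol=1e-12)

    def test_sixty_terms_match_high_order_series(self):
        """Truncation at 60 Legendre terms is within 0.1% of 200 terms."""
        rng = np.random.default_rng(0)
        sens = sim.synthetic_montage(24)[1]
        for _ in range(5):
            pos = rng.uniform(-1, 1, 3)
            pos = pos / np.linalg.norm(pos) * rng.uniform(20, 73)
            g60 = inv.dipole_potentials(pos, sens, n_terms=60)
            g200 = inv.dipole_potentials(pos, sens, n_terms=200)
            assert np.abs(g60 - g200).max() <= 1e-3 * np.abs(g200).max()

    def test_grid_node_outside_brain_is_rejected(self):
        sens = sim.synthetic_montage(20)[1]
        bad_grid = np.array([[0.0, 0.0, 10.0], [0.0, 0.0, 85.0]])
        with pytest.raises(ValueError, match="outside the brain shell"):
            ec.build_spherical_leadfield(sens, grid=bad_grid)

    def test_leadfield_rows_average_referenced(self, leadfield_small):
        col_means = leadfield_small.gain.mean(axis=0)
        assert np.abs(col_means).max() < 1e-12 * np.abs(leadfield_small.gain).max()

    def test_too_few_sensors_rejected(self):
        sens = sim.synthetic_montage(8)[1]
        with pytest.raises(ValueError, match="16 sensors"):
            ec.build_spherical_leadfield(sens, grid=np.zeros((1, 3)))


class TestEloreta:
    def test_one_iteration_weights_match_hand_computation(self):
        """First fixed-point step against explicit scipy matrix arithmetic."""
        rng = np.random.default_rng(3)
        gain = rng.standard_normal((3, 6))
        gain -= gain.mean(axis=0, keepdims=True)
        lf = inv.LeadfieldModel(
            gain, np.zeros((2, 3)), 1.0, inv.DEFAULT_RADII,
            inv.DEFAULT_CONDUCTIVITIES, np.zeros((3, 3)),
        )
        alpha_frac = 0.05
        with pytest.warns(RuntimeWarning, match="did not converge"):
            op = ec.compute_eloreta_operator(lf, alpha_frac=alpha_frac, max_iter=1)

        H = np.eye(3) - np.ones((3, 3)) / 3
        C = gain @ gain.T  # W = identity at initialization
        alpha = alpha_frac * np.trace(C) / 3
        M = np.linalg.pinv(C + alpha * H)
        for j in range(2):
            Kj = gain[:, 3 * j: 3 * j + 3]
            expected = scipy.linalg.sqrtm(Kj.T @ M @ Kj)
            assert np.allclose(op.weights[j], np.real(expected), atol=1e-10)

    def test_transfer_linear_in_data(self, operator_small):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(operator_small.transfer.shape[1])
        assert np.allclose(
            operator_small.transfer @ (5.0 * v),
            5.0 * (operator_small.transfer @ v),
        )

    def test_zero_localization_error(self, leadfield_small, operator_small):
        """Noiseless single-dipole fields localize to the true node, exactly."""
        rng = np.random.default_rng(7)
        nodes = rng.integers(0, leadfield_small.n_grid, 20)
        for j in nodes:
            q = rng.standard_normal(3)
            v = leadfield_small.gain_at(int(j)) @ q
            assert inv.localize_single_dipole(operator_small, v) == int(j)

    def test_nonconvergence_warns_but_returns(self, leadfield_small):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            op = ec.compute_eloreta_operator(leadfield_small, max_iter=2)
        assert not op.converged
        assert op.transfer.shape == (leadfield_small.n_grid * 3,
                                     leadfield_small.n_sensors)

    def test_invalid_alpha_rejected(self, leadfield_small):
        with pytest.raises(ValueError, match="alpha_frac"):
            ec.compute_eloreta_operator(leadfield_small, alpha_frac=0.0)


class TestROIExtraction:
    def _noiseless_recording(
        self, leadfield, source_mni, duration=30.0, seed=0, noise=0.0
    ):
        cfg = ec.SimulationConfig(
            n_sources=len(source_mni),
            source_positions_mni=np.asarray(source_mni),
            duration=duration,
            rate=250.0,
            sensor_noise_sigma=noise,
            seed=seed,
        )
        src, gt = ec.simulate_coupled_sources(cfg)
        rec = ec.project_to_sensors(src, leadfield, cfg, gt)
        return filter_and_rereference(rec), src

    def test_reference_requirement(self, leadfield_roi, operator_roi, table):
        rec, _ = self._noiseless_recording(leadfield_roi, [[-1.0, -17.0, 55.0]])
        raw = rec.copy_with(reference="recording-ref")
        with pytest.raises(ValueError, match="average-referenced"):
            ec.extract_roi_timecourses(raw, leadfield_roi, operator_roi, table)

    def test_sign_flip_symmetry(self, leadfield_roi, operator_roi, table):
        rec, _ = self._noiseless_recording(leadfield_roi, [[-1.0, -17.0, 55.0]])
        a = ec.extract_roi_timecourses(rec, leadfield_roi, operator_roi, table)
        flipped = rec.copy_with(data=-rec.data)
        b = ec.extract_roi_timecourses(flipped, leadfield_roi, operator_roi, table)
        for i in range(len(table)):
            r = np.corrcoef(a.data[i], b.data[i])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-9

    def test_lsma_source_lands_in_lsma_roi(self, leadfield_roi, operator_roi, table):
        """A source planted at lSMA is seen most strongly by the MOT seeds.

        Sensor noise breaks the rank-1 degeneracy of a noiseless single-source
        recording, so ROI estimates with weaker gain toward the source decay.
        """
        rec, src = self._noiseless_recording(
            leadfield_roi, [[-1.0, -17.0, 55.0]], duration=60.0, noise=1.0
        )
        roi_tc = ec.extract_roi_timecourses(rec, leadfield_roi, operator_roi, table)
        cors = np.abs([
            np.corrcoef(roi_tc.data[i], src[0])[0, 1] for i in range(len(table))
        ])
        lsma = table.roi_index("lSMA")
        other_networks = [
            i for i in range(len(table)) if table.networks[i] != "MOT"
        ]
        assert cors[lsma] > max(cors[i] for i in other_networks)

    def test_member_nodes_within_sphere_or_snapped(
        self, leadfield_roi, operator_roi, table
    ):
        rec, _ = self._noiseless_recording(leadfield_roi, [[-1.0, -17.0, 55.0]])
        roi_tc = ec.extract_roi_timecourses(rec, leadfield_roi, operator_roi, table)
        assert len(roi_tc.member_nodes) == len(table)
        for i, nodes in enumerate(roi_tc.member_nodes):
            assert len(nodes) >= 1
            d = np.linalg.norm(
                leadfield_roi.grid[nodes] - table.coords_head[i], axis=1
            )
            # ROI centres are grid nodes here, so the sphere is never empty
            assert d.min() < 1e-9 and d.max() <= 6.0

    def test_noiseless_envelope_reconstruction(
        self, leadfield_roi, operator_roi, table
    ):
        """Inverse-projected ROI course tracks its own source closely."""
        rec, src = self._noiseless_recording(
            leadfield_roi, [[-1.0, -17.0, 55.0]], duration=60.0
        )
        roi_tc = ec.extract_roi_timecourses(rec, leadfield_roi, operator_roi, table)
        lsma = table.roi_index("lSMA")
        assert abs(np.corrcoef(roi_tc.data[lsma], src[0])[0, 1]) > 0.8


class TestGeometry:
    def test_min_pairwise_roi_distance(self, table):
        assert table.min_pairwise_distance() >= 15.0

    def test_network_membership_counts(self, table):
        counts = {n: len(table.members(n)) for n in ("DMN", "DAN", "VAN",
                                                     "LANG", "MOT", "VIS")}
        assert counts == {"DMN": 4, "DAN": 4, "VAN": 2, "LANG": 2,
                         "MOT": 5, "VIS": 4}

    def test_all_rois_inside_brain_shell(self, table):
        assert np.linalg.norm(table.coords_head, axis=1).max() < 74.0
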