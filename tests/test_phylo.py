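"""Trees, shared-ancestry covariance, pGLS and lambda identifiability."""

import numpy as np
import pytest

from spiroscale import phylo as ph
from spiroscale.scaling import loglog_ols
from spiroscale.synth import GeneratorConfig, generate_specimens, generate_tree


class TestParseNewick:
    def test_two_tips_unit_depths(self):
        t = ph.parse_newick("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert t.tip_depths() == {"A": 1.0, "B": 1.0}

    def test_unit_lengths_from_topology_only(self):
        t = ph.parse_newick("((A,B),C);", unit_branch_lengths=True)
        d = t.tip_depths()
        assert d["A"] == d["B"] == 2.0
        assert d["C"] == 1.0

    def test_lengths_absent_defaults_to_unit(self):
        t = ph.parse_newick("((A,B),C);")
        assert t.tip_depths()["A"] == 2.0

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ph.NewickParseError, match="duplicate"):
            ph.parse_newick("(A:1,A:1);")

    def test_malformed_rejected(self):
        with pytest.raises(ph.NewickParseError):
            ph.parse_newick("((A:1,B:1;")

    def test_polytomy_allowed(self):
        t = ph.parse_newick("(A:1,B:1,C:1,D:1);")
        assert len(t.tip_labels) == 4


class TestPhyloCovariance:
    def test_star_tree_is_identity(self):
        t = ph.parse_newick("(A:1,B:1,C:1);")
        for lam in (0.0, 0.5, 1.0):
            V = ph.phylo_covariance(t, ["A", "B", "C"], lam=lam, jitter=0.0)
            assert np.allclose(V.matrix, np.eye(3))

    def test_hand_shared_branch_computation(self):
        t = ph.parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        V = ph.phylo_covariance(t, ["A", "B", "C"], lam=1.0, jitter=0.0)
        assert V.matrix[0, 1] == pytest.approx(0.5)
        assert V.matrix[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(V.matrix), 1.0)

    def test_lambda_zero_diagonalizes(self):
        t = ph.parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        V = ph.phylo_covariance(t, ["A", "B", "C"], lam=0.0, jitter=0.0)
        assert np.allclose(V.matrix, np.diag(V.tip_depths))

    def test_conspecific_specimens_share_tip_depth(self):
        t = ph.parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        V = ph.phylo_covariance(t, ["A", "A", "C"], lam=1.0, jitter=1e-6)
        assert V.matrix[0, 1] == pytest.approx(1.0)
        assert V.matrix[0, 0] == pytest.approx(1.0 * (1 + 1e-6))

    def test_tip_order_invariance(self):
        t = ph.parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        V1 = ph.phylo_covariance(t, ["A", "B", "C"], lam=1.0, jitter=0.0)
        V2 = ph.phylo_covariance(t, ["C", "A", "B"], lam=1.0, jitter=0.0)
        perm = [1, 2, 0]  # positions of A,B,C inside V2's ordering
        assert np.allclose(V1.matrix, V2.matrix[np.ix_(perm, perm)])

    def test_positive_semidefinite(self):
        cfg = GeneratorConfig(seed=5)
        tree = generate_tree(cfg)
        species = [s for s in cfg.species_names() for _ in range(2)]
        V = ph.phylo_covariance(tree, species, lam=1.0)
        assert np.all(np.linalg.eigvalsh(V.matrix) > 0)

    def test_unknown_species_named_in_error(self):
        t = ph.parse_newick("(A:1,B:1);")
        with pytest.raises(ph.SpeciesLookupError, match="Z"):
            ph.phylo_covariance(t, ["A", "Z"])


class TestPGLS:
    masses = np.logspace(-1, 1, 8)

    def _values(self, rng, slope=0.67, sd=0.1):
        return 10 ** (
            0.3 + slope * np.log10(self.masses) + sd * rng.standard_normal(8)
        )

    def test_identity_covariance_equals_ols(self, rng):
        y = self._values(rng)
        V = ph.PhyloCovariance(np.eye(8), 0.0, ("x",) * 8, np.ones(8))
        g = ph.pgls_fit(self.masses, y, V)
        o = loglog_ols(self.masses, y)
        assert g.slope == pytest.approx(o.slope, abs=1e-10)
        assert g.intercept == pytest.approx(o.intercept, abs=1e-10)

    def test_scaled_identity_invariance(self, rng):
        y = self._values(rng)
        V1 = ph.PhyloCovariance(np.eye(8), 0.0, ("x",) * 8, np.ones(8))
        V2 = ph.PhyloCovariance(2.0 * np.eye(8), 0.0, ("x",) * 8, np.ones(8))
        g1 = ph.pgls_fit(self.masses, y, V1)
        g2 = ph.pgls_fit(self.masses, y, V2)
        assert g1.slope == pytest.approx(g2.slope, abs=1e-12)
        assert g1.intercept == pytest.approx(g2.intercept, abs=1e-12)

    def test_matches_whitening_oracle_on_sister_pairs(self, rng):
        """Brute-force oracle: Cholesky-whiten then run plain OLS."""
        tree = ph.parse_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        species = list("ABCDEFGH")
        V = ph.phylo_covariance(tree, species, lam=1.0, jitter=0.0)
        y = self._values(rng)
        g = ph.pgls_fit(self.masses, y, V)

        L = np.linalg.cholesky(V.matrix)
        X = np.column_stack([np.ones(8), np.log10(self.masses)])
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, np.log10(y))
        beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        assert g.intercept == pytest.approx(beta[0], abs=1e-10)
        assert g.slope == pytest.approx(beta[1], abs=1e-10)

    def test_singular_covariance_reported(self, rng):
        y = self._values(rng)
        M = np.ones((8, 8))  # rank 1
        V = ph.PhyloCovariance(M, 1.0, ("x",) * 8, np.ones(8))
        with pytest.raises(ph.SingularCovarianceError, match="cond"):
            ph.pgls_fit(self.masses, y, V)


class TestLambdaDiagnostic:
    def test_constant_response_profile_exactly_flat(self):
        tree = ph.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        masses = np.array([0.1, 1.0, 5.0, 18.0])
        prof = ph.lambda_diagnostic(
            masses, np.ones(4) * 3.7, list("ABCD"), tree
        )
        assert prof.degenerate
        assert prof.flatness == 0.0
        assert np.all(prof.loglik == prof.loglik[0])
        assert not prof.is_identifiable()
        assert ph.lambda_prior_posterior_overlap(prof) == pytest.approx(1.0)

    def test_lambda_zero_recovered_at_large_n(self, rng):
        """Independent residuals: profile maximum near lambda = 0."""
        cfg = GeneratorConfig(
            seed=31,
            n_species=40,
            specimens_per_species=(1,) * 40,
        )
        tree = generate_tree(cfg)
        species = cfg.species_names()
        masses = 10 ** rng.uniform(-1, 1, 40)
        y = 10 ** (0.3 + 0.67 * np.log10(masses) + 0.3 * rng.standard_normal(40))
        prof = ph.lambda_diagnostic(masses, y, species, tree)
        assert prof.lambda_hat <= 0.2

    def test_nonidentifiable_at_study_design(self):
        """17 specimens / 10 species, simulated lambda = 0.5: the
        ancestry-level profile is flat in most runs (the design cannot
        pin lambda down)."""
        from spiroscale.morphometry import specimen_totals

        flat_runs = 0
        nsim = 40
        for i in range(nsim):
            cfg = GeneratorConfig(seed=300 + i, lambda_signal=0.5, phylo_sd=0.1)
            tree = generate_tree(cfg)
            specimens = generate_specimens(cfg, tree=tree)
            masses = np.array([s.mass for s in specimens])
            species = [s.species for s in specimens]
            y = np.array([specimen_totals(s).diff_index for s in specimens])
            prof = ph.lambda_diagnostic(
                masses, y, species, tree, level="species"
            )
            if not prof.is_identifiable():
                flat_runs += 1
        assert flat_runs / nsim > 0.5

    def test_specimen_level_profile_excludes_lambda_one(self):
        """Replicate conspecifics that disagree mechanically reject
        lambda near 1, so the specimen-level profile is steep."""
        cfg = GeneratorConfig(seed=301, lambda_signal=0.5, phylo_sd=0.1)
        tree = generate_tree(cfg)
        specimens = generate_specimens(cfg, tree=tree)
        masses = np.array([s.mass for s in specimens])
        species = [s.species for s in specimens]
        from spiroscale.morphometry import specimen_totals

        y = np.array([specimen_totals(s).diff_index for s in specimens])
        prof = ph.lambda_diagnostic(masses, y, species, tree)
        assert prof.is_identifiable()
        assert prof.loglik[-1] < prof.loglik.max() - 10
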