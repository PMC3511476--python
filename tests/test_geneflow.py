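"""FST estimation, migration inversion, and the binomial gene-flow test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from argscan.arg import PopulationMap
from argscan.geneflow import (binomial_gene_flow_test, fst_from_m, fst_hudson,
                              gene_flow_report, m_from_fst,
                              migration_distribution)


@pytest.fixture(scope="module")
def popmap4():
    return PopulationMap.from_pairs([("a1", "A"), ("a2", "A"),
                                     ("b1", "B"), ("b2", "B")])


SAMPLES4 = ["a1", "a2", "b1", "b2"]


class TestFst:
    def test_identical_populations_zero(self, popmap4):
        h = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0], [1, 0, 1]])
        rec = fst_hudson(h, SAMPLES4, popmap4, ("A", "B"))
        assert rec.fst == pytest.approx(0.0)

    def test_fixed_differences_give_one(self, popmap4):
        h = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        rec = fst_hudson(h, SAMPLES4, popmap4, ("A", "B"))
        assert rec.fst == pytest.approx(1.0)

    def test_hand_computed_toy_matrix(self, popmap4):
        # within-A: a1-a2 differ at 1 site; within-B: b1-b2 at 2 sites
        # -> within = 1.5; cross pairs differ at 2,2,3,1 sites -> between 2
        h = np.array([[0, 0, 0],
                      [0, 1, 0],
                      [1, 0, 1],
                      [1, 1, 0]])
        rec = fst_hudson(h, SAMPLES4, popmap4, ("A", "B"))
        assert rec.within == pytest.approx(1.5)
        assert rec.between == pytest.approx(2.0)
        assert rec.fst == pytest.approx(0.25)

    def test_missing_data_lowers_weight(self, popmap4):
        h = np.array([[0, -1], [0, 1], [1, 0], [1, 1]])
        rec = fst_hudson(h, SAMPLES4, popmap4, ("A", "B"), gene_length=100)
        assert rec.weight == pytest.approx(50.0)

    def test_monomorphic_between_flagged(self, popmap4):
        h = np.zeros((4, 0), dtype=int)
        rec = fst_hudson(h, SAMPLES4, popmap4, ("A", "B"))
        assert rec.fst is None and not rec.valid

    def test_single_sample_population_rejected(self):
        pm = PopulationMap.from_pairs([("a1", "A"), ("b1", "B"), ("b2", "B")])
        h = np.zeros((3, 2), dtype=int)
        with pytest.raises(ValueError):
            fst_hudson(h, ["a1", "b1", "b2"], pm, ("A", "B"))


class TestMigrationInversion:
    def test_round_trip_identity(self):
        assert m_from_fst(fst_from_m(1.0, 5), 5) == pytest.approx(1.0)

    def test_limits(self):
        assert m_from_fst(1.0) == 0.0
        assert m_from_fst(0.0) == math.inf

    def test_strictly_decreasing_in_fst(self):
        fsts = np.linspace(0.05, 0.95, 19)
        ms = [m_from_fst(f, 5) for f in fsts]
        assert all(a > b for a, b in zip(ms, ms[1:]))

    def test_weighted_percentiles(self):
        from argscan.geneflow import FstRecord
        recs = [FstRecord("g1", "A", "B", 1, 2, 0.5, 100, 1.0),
                FstRecord("g2", "A", "B", 1, 4, 0.75, 100, 3.0)]
        est = migration_distribution(recs, d=5)
        assert est.percentiles[50.0] == pytest.approx(m_from_fst(0.75, 5))
        assert est.pooled == est.percentiles[50.0]

    def test_single_gene_constant_percentiles(self):
        from argscan.geneflow import FstRecord
        recs = [FstRecord("g1", "A", "B", 1, 2, 0.5, 100, 1.0)]
        est = migration_distribution(recs, d=5)
        assert len(set(est.percentiles.values())) == 1

    def test_parameter_recovery_from_simulated_genes(self):
        # genes simulated at known M: pooled median within a factor of two
        from argscan import simulate as sim
        from argscan.island import Demography
        for M in (0.5, 2.0):
            demo = Demography.symmetric_island(d=5, M=M, samples=(3, 3, 3, 2, 2))
            recs = []
            pm = None
            for s in range(60):
                g = sim.simulate_gene(1000, 0.0, demo, seed=1000 + s,
                                      target_snps=40)
                if pm is None:
                    pm = PopulationMap.from_pairs(
                        [(x, x.rsplit("_", 1)[0]) for x in g.arg.samples])
                recs.append(fst_hudson(g.matrix, list(g.arg.samples), pm,
                                       ("pop1", "pop2"), gene_id=g.gene_id,
                                       gene_length=g.length))
            est = migration_distribution(recs, d=5)
            assert M / 2 < est.pooled < 2 * M


class TestBinomialTest:
    def test_zero_observation_gives_one(self):
        res = binomial_gene_flow_test(0, 10, 0.3, 100, 0.5)
        assert res.p_value == pytest.approx(1.0)
        assert res.p_corrected == 1.0

    def test_closed_form_tail(self):
        # x_eff = n_eff = 10 at p0 = 1/2: p = 2^-10, Bonferroni x5
        res = binomial_gene_flow_test(10, 10, 0.5, 20, 0.5, n_tests=5)
        assert res.n_eff == 10 and res.x_eff == 10
        assert res.p_value == pytest.approx(2 ** -10)
        assert res.p_corrected == pytest.approx(5 * 2 ** -10)

    def test_rounding_is_conservative(self):
        res = binomial_gene_flow_test(7, 13, 0.3, 10, 0.55)
        assert res.n_eff == 6  # ceil(5.5)
        assert res.x_eff == 3  # floor(7 * 6 / 13)

    @given(st.integers(1, 60), st.integers(0, 60),
           st.floats(0.05, 0.95), st.integers(1, 200),
           st.floats(0.01, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_scaling_never_smaller_p_than_unscaled(self, n, x, p0, genes, frac):
        x = min(x, n)
        res = binomial_gene_flow_test(x, n, p0, genes, frac)
        from scipy import stats as ss
        if res.n_eff <= n:
            unscaled = float(ss.binom.sf(
                math.ceil(x * res.n_eff / n) - 1, res.n_eff, p0))
            assert res.p_value >= unscaled - 1e-12

    def test_monotone_in_x_and_p0(self):
        ps = [binomial_gene_flow_test(x, 20, 0.3, 100, 0.2).p_value
              for x in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        ps = [binomial_gene_flow_test(12, 20, p0, 100, 0.2).p_value
              for p0 in (0.1, 0.3, 0.5, 0.7)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_report_layout(self):
        import pandas as pd
        tally = pd.DataFrame([
            {"population": "P", "k": 3, "n_RA": 8, "n_RO": 4,
             "n_genes": 100, "frac_outgroup": 0.1},
            {"population": "Q", "k": 2, "n_RA": 0, "n_RO": 0,
             "n_genes": 100, "frac_outgroup": 0.0},
        ])
        rep = gene_flow_report(tally, {1.0: {3: 0.316, 2: 0.307},
                                       10.0: {3: 0.367, 2: 0.338}},
                               n_tests=5)
        assert list(rep.columns) == ["M", "P", "Q"]
        assert len(rep) == 2
        assert math.isnan(rep["Q"].iloc[0])
        # power shrinks as the assumed M grows
        assert rep["P"].iloc[0] <= rep["P"].iloc[1] + 1e-12
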