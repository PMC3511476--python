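"""True-ARG simulator: consistency, moments, reproducibility, truth logs."""

import numpy as np
import pytest

from argscan import hapio
from argscan.arg import PopulationMap, local_tree, marginal_trees
from argscan.island import Demography
from argscan.scan import outgroup_intervals
from argscan.simulate import (AdmixturePulse, GenomeDesign, model_i_demography,
                              model_ii_demography, simulate_gene,
                              simulate_genome, truth_log_frame)

PANMICTIC = Demography(deme_sizes=(1.0,), migration=((0.0,),),
                       sample_sizes=(10,), labels=("pop",))


class TestSingleGene:
    def test_zero_rho_gives_single_tree(self):
        g = simulate_gene(1000, 0.0, PANMICTIC, seed=1, target_snps=12)
        assert g.arg.breakpoints == []
        assert len(marginal_trees(g.arg)) == 1
        assert len(g.sites) == 12

    def test_matrix_consistent_with_local_trees(self):
        g = simulate_gene(1500, 3e-4, model_i_demography(), seed=5,
                          target_snps=30)
        order = list(g.arg.samples)
        for j, s in enumerate(g.sites):
            carriers = {order[i] for i in range(len(order))
                        if g.matrix[i, j] == 1}
            # derived carriers equal the leaf set under the mutation's edge
            edge = next(e for e in g.arg.edges if s in e.mutations)
            tree = local_tree(g.arg, s)
            clades = tree.clades()
            # the mutation's child node may be contracted out of the tree;
            # its descendant set at the site is the truth
            desc = g.arg.descendants_at(edge.child, s)
            assert carriers == set(desc)
            assert 0 < len(carriers) < len(order)

    def test_truth_log_matches_emitted_breakpoints(self):
        g = simulate_gene(2000, 4e-4, model_i_demography(), seed=9,
                          target_snps=20)
        rec_events = [e for e in g.events if e["type"] == "recombination"]
        assert sorted(e["breakpoint"] for e in rec_events) == g.arg.breakpoints
        desc = g.recombination_descendants()
        for nid in g.arg.recombination_nodes:
            bp = g.arg.nodes[nid].breakpoint
            # descendants at the breakpoint site agree with the truth log
            assert g.arg.descendants_at(nid, bp) == desc[nid]

    def test_scan_classification_agrees_with_truth_log(self):
        pm = None
        checked = 0
        for seed in range(120):
            if checked >= 8:
                break
            g = simulate_gene(2000, 4e-4, model_i_demography(), seed=seed,
                              target_snps=10)
            if pm is None:
                pm = PopulationMap.from_pairs(
                    [(s, s.rsplit("_", 1)[0]) for s in g.arg.samples])
            truth = {e["node"]: e for e in g.events
                     if e["type"] == "recombination"}
            for iv in outgroup_intervals(g.arg, pm):
                for ev in iv.boundary_events:
                    rec = truth[ev.node_id]
                    # left boundaries are read on the suffix side of the
                    # breakpoint, right boundaries on the prefix side
                    side = "descendants_suffix" \
                        if iv.interval[0] == ev.breakpoint + 1 else "descendants"
                    assert ev.descendants == rec[side]
                    assert ev.classification in ("R_A", "R_O")
                    checked += 1
        assert checked >= 8

    def test_pulse_requires_valid_config(self):
        with pytest.raises(ValueError):
            AdmixturePulse(recipient=0, donor=5, time=1.0, fraction=1.5)
        demo, pulse = model_ii_demography()
        bad = AdmixturePulse(recipient=0, donor=5, time=100.0, fraction=0.5)
        with pytest.raises(ValueError):
            simulate_gene(500, 0.0, demo, pulse=bad, seed=0)

    def test_coalescent_moments_panmictic(self):
        # E[height] = 2(1 - 1/n), E[length] = 2 sum 1/i for the standard
        # coalescent; checked at n=10 without recombination
        n = 10
        heights = []
        lengths = []
        for s in range(400):
            g = simulate_gene(100, 0.0, PANMICTIC, seed=7000 + s,
                              target_snps=0)
            root = g.arg.root
            heights.append(g.node_times[root])
            lengths.append(sum(
                g.node_times[e.parent] - g.node_times[e.child]
                for e in g.arg.edges))
        eh = 2 * (1 - 1 / n)
        el = 2 * sum(1 / i for i in range(1, n))
        assert np.mean(heights) == pytest.approx(eh, rel=0.1)
        assert np.mean(lengths) == pytest.approx(el, rel=0.1)

    def test_watterson_site_counts(self):
        # Poisson-mutation mode: mean segregating sites ~ theta * sum 1/i
        theta_bp, L, n = 0.02, 500, 10
        counts = [len(simulate_gene(L, 0.0, PANMICTIC, seed=8000 + s,
                                    target_snps=None,
                                    theta_per_bp=theta_bp).sites)
                  for s in range(300)]
        expected = theta_bp * L * sum(1 / i for i in range(1, n))
        assert np.mean(counts) == pytest.approx(expected, rel=0.12)


class TestGenome:
    def test_reproducible_from_master_seed(self):
        design = GenomeDesign(n_genes=4, gene_length=800)
        a, ma = simulate_genome(design, model_i_demography(), seed=3)
        b, mb = simulate_genome(design, model_i_demography(), seed=3)
        assert ma.equals(mb)
        for ga, gb in zip(a, b):
            assert ga.sites == gb.sites
            assert np.array_equal(ga.matrix, gb.matrix)
            assert ga.arg.breakpoints == gb.arg.breakpoints

    def test_structure_raises_differentiation(self):
        from argscan.geneflow import fst_hudson
        vals = {}
        for M in (0.1, 10.0):
            demo = Demography.symmetric_island(d=5, M=M)
            fsts = []
            pm = None
            for s in range(30):
                g = simulate_gene(800, 0.0, demo, seed=8100 + s,
                                  target_snps=30)
                if pm is None:
                    pm = PopulationMap.from_pairs(
                        [(x, x.rsplit("_", 1)[0]) for x in g.arg.samples])
                rec = fst_hudson(g.matrix, list(g.arg.samples), pm,
                                 ("pop1", "pop2"))
                if rec.valid:
                    fsts.append(rec.fst)
            vals[M] = np.mean(fsts)
        assert vals[0.1] > vals[10.0]

    def test_truth_log_frame_layout(self):
        g = simulate_gene(1000, 4e-4, model_i_demography(), seed=2,
                          target_snps=5)
        df = truth_log_frame(g)
        assert {"gene", "type", "time", "node", "descendants"} <= set(df.columns)
        assert (df.type == "coalescence").sum() >= 12

    def test_ms_block_round_trip(self, tmp_path):
        g = simulate_gene(1000, 0.0, PANMICTIC, seed=4, target_snps=15)
        path = tmp_path / "block.txt"
        hapio.write_ms(g.matrix, g.sites, g.length, str(path))
        blocks = hapio.read_ms(str(path), length=g.length)
        assert len(blocks) == 1
        mat, pos = blocks[0]
        assert np.array_equal(mat, g.matrix)
        assert pos == g.sites


class TestExternalOracle:
    def test_island_tree_heights_match_msprime(self):
        """Structured-coalescent timescale cross-checked against msprime.

        Same model on both sides: five islands of size 1 (in units of the
        reference 2N), pair coalescence rate 1 within a deme, per-lineage
        migration rate M/2 split over the other demes.
        """
        import msprime

        M, d = 1.0, 5
        demo = Demography.symmetric_island(d=d, M=M)
        mine = []
        for s in range(250):
            g = simulate_gene(100, 0.0, demo, seed=9200 + s, target_snps=0)
            mine.append(g.node_times[g.arg.root])

        md = msprime.Demography()
        for i in range(d):
            md.add_population(initial_size=1.0)  # pair rate 1 per unit
        rate = 0.5 * M / (d - 1)
        md.migration_matrix = np.array(
            [[0 if i == j else rate for j in range(d)] for i in range(d)],
            dtype=float)
        samples = {f"pop_{i}": n for i, n in enumerate((3, 3, 3, 2, 2))}
        heights = []
        for ts in msprime.sim_ancestry(samples=samples, demography=md,
                                       ploidy=1, num_replicates=250,
                                       random_seed=77):
            heights.append(ts.first().time(ts.first().root))
        se = (np.std(mine) ** 2 / len(mine)
              + np.std(heights) ** 2 / len(heights)) ** 0.5
        assert abs(np.mean(mine) - np.mean(heights)) < 3 * se
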