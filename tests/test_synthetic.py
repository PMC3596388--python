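import numpy as np
import pytest
from scipy.stats import binom

from tsnet.bicluster import enumerate_biclusters_oracle, ql_biclustering
from tsnet.datatypes import GeneStateMatrix
from tsnet.discretize import em_train, init_model, viterbi_decode
from tsnet.synthetic import generate_benchmark, generate_dataset, generate_network


def test_same_seed_reproduces_bitwise():
    ds1, t1 = generate_dataset(n_pos=5, n_neg=4, n_genes=15, T=5, seed=17,
                               n_disc_modules=1, decoy_modules=1, module_size=3)
    ds2, t2 = generate_dataset(n_pos=5, n_neg=4, n_genes=15, T=5, seed=17,
                               n_disc_modules=1, decoy_modules=1, module_size=3)
    np.testing.assert_array_equal(
        np.nan_to_num(ds1.values), np.nan_to_num(ds2.values)
    )
    np.testing.assert_array_equal(ds1.mask, ds2.mask)
    for p in ds1.patient_ids:
        np.testing.assert_array_equal(t1.true_states[p], t2.true_states[p])
    net1, _ = generate_network(ds1.gene_ids, [4], 0.7, 0.1, seed=3)
    net2, _ = generate_network(ds1.gene_ids, [4], 0.7, 0.1, seed=3)
    assert net1.edges == net2.edges


def test_network_deterministic_module_is_clique():
    genes = [f"g{i}" for i in range(6)]
    net, modules = generate_network(genes, [3], p_in=1.0, p_out=0.0, seed=0)
    assert set(net.edges) == {("g0", "g1"), ("g0", "g2"), ("g1", "g2")}
    assert modules[0] == ["g0", "g1", "g2"]


def test_no_cross_module_edges_at_p_out_zero():
    genes = [f"g{i}" for i in range(12)]
    net, modules = generate_network(genes, [4, 4], p_in=0.9, p_out=0.0, seed=1)
    module_of = {g: m for m, gl in modules.items() for g in gl}
    for u, v in net.edges:
        assert module_of.get(u) == module_of.get(v)


def test_invalid_probabilities_error():
    with pytest.raises(ValueError):
        generate_network(["a", "b"], [2], p_in=0.2, p_out=0.5, seed=0)


def test_edge_count_within_binomial_band():
    genes = [f"g{i}" for i in range(12)]
    p_in, p_out = 0.6, 0.1
    in_pairs, total_pairs = 6, 66
    expected_p = (in_pairs * p_in + (total_pairs - in_pairs) * p_out) / total_pairs
    total = sum(
        generate_network(genes, [4], p_in, p_out, seed=s)[0].n_edges
        for s in range(100)
    )
    n_trials = 100 * total_pairs
    lo, hi = binom.ppf([0.005, 0.995], n_trials, expected_p)
    assert lo <= total <= hi


def test_noiseless_data_decodes_to_true_states():
    """In the noiseless limit, decoding with the generating parameters
    recovers the true state paths exactly."""
    from tsnet.discretize import HmmGmmModel

    ds, truth = generate_dataset(
        n_pos=6, n_neg=5, n_genes=12, T=6, noise_sd=0.0, missing_rate=0.0, seed=4,
        n_disc_modules=1, decoy_modules=1, module_size=3
    )
    Q, n = 3, ds.n_genes
    model = HmmGmmModel(
        Q, n,
        pi=np.full(Q, 1 / Q),
        A=np.full((Q, Q), 1 / Q),
        w=np.full((Q, n), 1 / n),
        mu=np.tile(np.arange(1, Q + 1, dtype=float)[:, None], (1, n)),
        sigma=np.full((Q, n), 0.1),
        sigma_floor=1e-6,
    )
    decoded = viterbi_decode(model, ds)
    for p in ds.patient_ids:
        np.testing.assert_array_equal(decoded[p].states, truth.true_states[p])


def test_planted_bicluster_appears_in_oracle_output():
    ds, truth = generate_dataset(
        n_pos=3, n_neg=3, n_genes=12, T=7, noise_sd=0.0, missing_rate=0.0,
        n_disc_modules=1, decoy_modules=0, module_size=5,
        disc_window=(2, 5), share_window=(2, 5), seed=8,
    )
    planted = truth.planted_biclusters[1][0]
    assert (planted.t_start, planted.t_end) == (2, 5)
    pid = ds.patient_ids[0]  # a positive-class patient
    sm = GeneStateMatrix(ds.gene_ids, ds.time_points, truth.true_states[pid], 3)
    found = enumerate_biclusters_oracle(sm, ml=2, mo=3)
    hits = [
        bc for bc in found
        if set(planted.genes) <= set(bc.genes)
        and bc.t_start <= planted.t_start
        and bc.t_end >= planted.t_end
    ]
    assert hits, "planted module window not recovered"


def test_pipeline_recovers_planted_biclusters_at_low_noise():
    """Fitting, decoding and biclustering the benchmark cohort at noise
    sd 0.25 recovers the planted discriminative modules: the mean (over
    patients and planted modules) gene-set Jaccard between each planted
    bicluster and its best-matching extracted bicluster is >= 0.8.

    The aggregate is the right statement: any positive noise level
    occasionally flips one state of one module gene in one patient,
    which removes that gene from the full-window bicluster, so a
    universal per-patient bound cannot hold.
    """
    from tsnet.synthetic import baranzini_like

    ds, net, truth = baranzini_like(seed=0, missing_rate=0.0)
    model = em_train(init_model(ds, Q=3), ds)
    decoded = viterbi_decode(model, ds)
    bests = []
    for i, pid in enumerate(ds.patient_ids):
        lab = int(ds.labels[i])
        biclusters = ql_biclustering(decoded[pid], ml=2, mo=2)
        for planted in truth.planted_biclusters[lab]:
            target = set(planted.genes)
            bests.append(
                max(
                    (
                        len(target & set(bc.genes)) / len(target | set(bc.genes))
                        for bc in biclusters
                    ),
                    default=0.0,
                )
            )
    assert np.mean(bests) >= 0.8, f"mean recovery Jaccard {np.mean(bests):.3f}"


def test_missingness_always_leaves_one_value():
    ds, _ = generate_dataset(
        n_pos=4, n_neg=4, n_genes=8, T=4, missing_rate=0.9, seed=12,
        n_disc_modules=1, decoy_modules=1, module_size=3, disc_window=(2, 4)
    )
    assert ds.mask.any(axis=2).all()


def test_identical_class_programs_remove_signal():
    ds, truth = generate_dataset(
        n_pos=6, n_neg=5, n_genes=15, T=6, noise_sd=0.0, missing_rate=0.0,
        n_disc_modules=1, decoy_modules=1, module_size=4,
        identical_classes=True, seed=9,
    )
    pos = truth.true_states[ds.patient_ids[0]]
    neg = truth.true_states[ds.patient_ids[-1]]
    disc_rows = [
        ds.gene_ids.index(g)
        for m, genes in truth.module_genes.items()
        if truth.module_kind[m] == "discriminative"
        for g in genes
    ]
    np.testing.assert_array_equal(pos[disc_rows], neg[disc_rows])
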