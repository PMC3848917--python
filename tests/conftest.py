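import warnings

import pytest

warnings.filterwarnings("ignore", message=".*Bio.codonalign.*")

from dupstruct.classify import ClassifierConfig, classify_all
from dupstruct.pipeline import compute_metrics
from dupstruct.simulate import SimConfig, default_config, simulate


def small_config(seed: int, **overrides) -> SimConfig:
    """A scaled-down dataset (2 x 120 genes, ~10 pairs/mode) for fast tests."""
    from dupstruct.simulate import EventParams

    base = default_config(seed)
    d = dict(
        seed=seed,
        n_chromosomes=2,
        genes_per_chromosome=160,
        gene_length_codons=(80, 200),
        n_noise_hits=60,
        events={
            name: EventParams(10, ev.target_ks, ev.indel_rate,
                              ev.indel_length_p, ev.omega)
            for name, ev in base.events.items()
        },
    )
    d.update(overrides)
    return SimConfig(**d)


def classifier_config(cfg: SimConfig) -> ClassifierConfig:
    return ClassifierConfig(
        recent_outgroups=tuple(cfg.recent_outgroups),
        broad_outgroups=tuple(cfg.broad_outgroups),
    )


@pytest.fixture(scope="session")
def small_sim():
    """One scaled-down simulated dataset, shared across tests."""
    return simulate(small_config(11))


@pytest.fixture(scope="session")
def small_classified(small_sim):
    res = classify_all(
        small_sim.genes, small_sim.hits, small_sim.wgd_lists,
        small_sim.te_ids, small_sim.anchors, classifier_config(small_sim.config),
    )
    return small_sim, res


@pytest.fixture(scope="session")
def small_metrics(small_classified):
    sim, res = small_classified
    return sim, res, compute_metrics(res.pairs, sim.genes)


@pytest.fixture(scope="session")
def study_runs():
    """Classified study-condition runs (seeds 1-5), metrics without rates."""
    runs = {}
    for seed in range(1, 6):
        cfg = default_config(seed)
        sim = simulate(cfg)
        res = classify_all(sim.genes, sim.hits, sim.wgd_lists, sim.te_ids,
                           sim.anchors, classifier_config(cfg))
        metrics = compute_metrics(res.pairs, sim.genes, with_rates=False)
        runs[seed] = (sim, res, metrics)
    return runs
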