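"""Simulation-based recovery experiments.

End-to-end harness: generate a synthetic catalog, network, ground truth and
reads; quantify with the independent per-gene model and with the
network-regularized model (true, label-permuted and edge-ablated networks);
and score each estimate by the Pearson correlation between log2(pi + 1) of
estimate and truth over multi-isoform transcripts.  Both the test suite and
the reproduction script drive their experiments through this module so the
numbers they report come from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import TranscriptCatalog
from .compat import CompatibilityMatrix
from .model import QuantificationResult, net_rstq_fit
from .network import TranscriptNetwork, randomize_network
from .simulate import (
    SimulationParams,
    SimulationTruth,
    evaluate_recovery,
    random_transcript_network,
    simulate_reads,
    simulate_truth,
    synthetic_catalog,
)

__all__ = ["SimulatedDataset", "simulate_dataset", "recovery_experiment"]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds (< 2**31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % 2**31]


@dataclass
class SimulatedDataset:
    catalog: TranscriptCatalog
    net: TranscriptNetwork
    truth: SimulationTruth
    compat: CompatibilityMatrix
    seed: int


def simulate_dataset(
    n_genes: int = 100,
    seed: int = 0,
    n_reads: int = 200_000,
    avg_degree: float = 27.0,
    l_r: int = 76,
    params: SimulationParams = SimulationParams(),
) -> SimulatedDataset:
    """One complete synthetic dataset: catalog, network, truth and reads."""
    s_cat, s_net, s_truth, s_reads = _child_seeds(seed, 4)
    catalog = synthetic_catalog(n_genes, seed=s_cat)
    net = random_transcript_network(catalog, avg_degree=avg_degree, seed=s_net)
    truth = simulate_truth(catalog, net, params=params, seed=s_truth)
    compat = simulate_reads(truth, catalog, n_reads=n_reads, l_r=l_r, seed=s_reads)
    return SimulatedDataset(catalog, net, truth, compat, seed)


def _recovery_of_fit(
    res: QuantificationResult,
    data: SimulatedDataset,
    subset: str,
) -> float:
    return evaluate_recovery(res.pi, data.truth, net=data.net, subset=subset)


def recovery_experiment(
    n_seeds: int = 10,
    lams: tuple[float, ...] = (0.01, 0.1, 1.0),
    n_genes: int = 100,
    n_reads: int = 200_000,
    n_permutations: int = 20,
    removal_fractions: tuple[float, ...] = (0.1, 0.2, 0.9),
    base_seed: int = 0,
    subset: str = "all_multi_isoform",
    max_rounds: int = 50,
    permute_lam: float = 0.1,
) -> dict:
    """Parameter-recovery comparison of the network prior against the
    independent per-gene baseline.

    For each of ``n_seeds`` replicate datasets the baseline and the joint
    model at every lam in ``lams`` (true network) and every fraction in
    ``removal_fractions`` (edge-ablated network, lam = ``permute_lam``) are
    fitted and scored.  Label-permuted null networks (``n_permutations`` of
    them, lam = ``permute_lam``) are fitted on the first replicate.

    Returns a dict of per-replicate correlation lists plus their means.
    """
    seeds = _child_seeds(base_seed, n_seeds)
    out: dict = {
        "seeds": seeds,
        "base": [],
        "net": {lam: [] for lam in lams},
        "removal": {f: [] for f in removal_fractions},
        "permuted": [],
        "rounds": [],
    }
    for rep, seed in enumerate(seeds):
        data = simulate_dataset(n_genes=n_genes, seed=seed, n_reads=n_reads)
        res_base = net_rstq_fit(data.compat, None, lam=0.0, max_rounds=5)
        out["base"].append(_recovery_of_fit(res_base, data, subset))
        for lam in lams:
            res = net_rstq_fit(
                data.compat, data.net, lam=lam, init="base_em",
                max_rounds=max_rounds,
            )
            out["net"][lam].append(_recovery_of_fit(res, data, subset))
            if lam == permute_lam:
                out["rounds"].append(res.rounds)
        for frac in removal_fractions:
            ablated = randomize_network(
                data.net, "remove_fraction", fraction=frac, seed=seed
            )
            res = net_rstq_fit(
                data.compat, ablated, lam=permute_lam, init="base_em",
                max_rounds=max_rounds,
            )
            out["removal"][frac].append(_recovery_of_fit(res, data, subset))
        if rep == 0:
            for j in range(n_permutations):
                null = randomize_network(
                    data.net, "permute_labels", seed=_child_seeds(seed, j + 2)[-1]
                )
                res = net_rstq_fit(
                    data.compat, null, lam=permute_lam, init="base_em",
                    max_rounds=max_rounds,
                )
                out["permuted"].append(_recovery_of_fit(res, data, subset))

    out["mean_base"] = float(np.mean(out["base"]))
    out["mean_net"] = {lam: float(np.mean(v)) for lam, v in out["net"].items()}
    out["mean_removal"] = {
        f: float(np.mean(v)) for f, v in out["removal"].items()
    }
    out["median_permuted"] = (
        float(np.median(out["permuted"])) if out["permuted"] else None
    )
    return out
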