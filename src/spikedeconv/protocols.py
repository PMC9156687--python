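"""End-to-end experiment protocols: simulate, estimate, score.

Each protocol runs one of the benchmark designs (burst sweep, LIF grid,
noisy cohort, conductance network), returns a tidy DataFrame, and attaches
a reproducibility manifest (``df.attrs["manifest"]``) holding the exact
parameters and seeds: re-running the protocol with the manifest's arguments
reproduces the table bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from .correlograms import compute_ach, compute_cch, conditional_rate
from .deconvolution import deconvolve_cch
from .detection import burst_index, confusion_and_f1, detect_connection
from .lifsyn import LifSynConfig, calibrate_uepsp, run_rstg_experiment
from .network import build_network, simulate_network
from .pointproc import CohortSpec, NeuronSpec, PairSimConfig, generate_cohort, simulate_pair
from .predictors import make_predictor
from .transmission import estimate_stg

__all__ = [
    "burst_pair_config",
    "run_burst_sweep",
    "run_lif_grid",
    "run_cohort_benchmark",
    "run_network_experiment",
    "mse_table",
    "f1_table",
]

PREDICTORS = ("tails", "jitter", "median")


def _manifest(name: str, **params) -> dict:
    from . import __version__

    return {"protocol": name, "package_version": __version__, **params}


def burst_pair_config(
    br1: float = 0.4, stg: float = 0.04, duration: float = 833 * 60.0, seed: int = 0,
    inhibitory: bool = False,
) -> PairSimConfig:
    """The two-neuron burst-sweep configuration.

    Excitatory default: bursty Poisson presynaptic neuron (2 spk/s, BR1 as
    given), second-order-gamma postsynaptic neuron (8 spk/s), gain 0.04
    over 833 simulated minutes.  The inhibitory variant swaps the roles:
    second-order-gamma presynaptic at 8 spk/s, bursty Poisson postsynaptic
    at 2 spk/s, gain -0.02.
    """
    if inhibitory:
        return PairSimConfig(
            neuron1=NeuronSpec(rate=8.0, gamma=2),
            neuron2=NeuronSpec(rate=2.0, br1=br1),
            stg12=-abs(stg) if stg != 0.04 else -0.02,
            duration=duration,
            seed=seed,
        )
    return PairSimConfig(
        neuron1=NeuronSpec(rate=2.0, br1=br1),
        neuron2=NeuronSpec(rate=8.0, gamma=2),
        stg12=stg,
        duration=duration,
        seed=seed,
    )


def estimate_all_methods(pair, predictors=PREDICTORS, roi_ms=(0.0, 5.0), sign="auto"):
    """eSTG of one simulated pair for every predictor, with and without
    deconvolution.  Returns rows of (method, deconvolved, estg)."""
    cch = compute_cch(pair.s1, pair.s2)
    ach1 = compute_ach(pair.s1)
    ach2 = compute_ach(pair.s2)
    dcch = deconvolve_cch(cch, ach1, ach2).dcch
    rows = []
    for method in predictors:
        for deconv, histo in ((False, cch), (True, dcch)):
            est = estimate_stg(histo, method, roi_ms=roi_ms, sign=sign)
            rows.append({"method": method, "deconvolved": deconv, "estg": est.estg})
    return rows


def run_burst_sweep(
    br_grid=tuple(np.round(np.arange(0.0, 0.45, 0.05), 2)),
    n_reps: int = 30,
    duration: float = 833 * 60.0,
    stg: float = 0.04,
    inhibitory: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Burst-fraction sweep: eSTG accuracy vs presynaptic burstiness.

    For every burst fraction and repetition, a pair is simulated and the
    gain estimated with all predictors on the CCH and the dcCCH.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(br_grid) * n_reps)]
    rows = []
    k = 0
    for br in br_grid:
        for rep in range(n_reps):
            cfg = burst_pair_config(
                br1=float(br), stg=stg, duration=duration, seed=seeds[k],
                inhibitory=inhibitory,
            )
            pair = simulate_pair(cfg)
            sign = "inhibitory" if inhibitory else "excitatory"
            for row in estimate_all_methods(pair, sign=sign):
                rows.append({"br1": br, "rep": rep, "rstg": cfg.stg12, **row})
            k += 1
    df = pd.DataFrame(rows)
    df.attrs["manifest"] = _manifest(
        "burst_sweep", br_grid=list(map(float, br_grid)), n_reps=n_reps,
        duration=duration, stg=stg, inhibitory=inhibitory, seed=seed,
    )
    return df


def run_lif_grid(
    sigmas=(2.0, 3.0, 4.0, 5.0),
    uepsps=(0.5, 1.0, 1.5, 2.0),
    n_reps: int = 2,
    duration: float = 3600.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noise-by-uEPSP grid on the LIF-synapse model.

    For every grid cell and repetition, the synaptic conductance is
    calibrated to the target uEPSP, the pair is simulated with the synapse
    on and off (shared noise), and both the ground-truth gain (from the
    paired rates) and the tails-predictor estimate (from the CCH) are
    recorded.
    """
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(10000))
    g_for = {u: calibrate_uepsp(u) for u in uepsps}
    rows = []
    for sigma in sigmas:
        for uepsp in uepsps:
            for rep in range(n_reps):
                cfg = LifSynConfig(
                    sigma=sigma, g_syn=g_for[uepsp], duration=duration,
                    seed=next(seeds),
                )
                res = run_rstg_experiment(cfg)
                cch = compute_cch(res["presyn"], res["postsyn_syn"])
                estg = estimate_stg(cch, "tails", sign="excitatory").estg
                rows.append(
                    {
                        "sigma": sigma, "uepsp": uepsp, "rep": rep,
                        "g_syn": g_for[uepsp], "lambda2_syn": res["lambda2_syn"],
                        "lambda2_nosyn": res["lambda2_nosyn"],
                        "rstg": res["rstg"], "estg": estg,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["manifest"] = _manifest(
        "lif_grid", sigmas=list(map(float, sigmas)),
        uepsps=list(map(float, uepsps)), n_reps=n_reps, duration=duration,
        seed=seed,
    )
    return df


def run_cohort_benchmark(
    spec: CohortSpec | None = None,
    seed: int = 0,
    predictors=PREDICTORS,
    alpha: float = 0.001,
    roi_ms=(0.0, 5.0),
) -> pd.DataFrame:
    """Noisy-cohort benchmark: estimation and detection per pair.

    One row per (pair, predictor, deconvolved) combination, carrying the
    ground truth, the signed eSTG (sign chosen automatically, as for real
    data), and the detection label at *alpha*.
    """
    spec = spec or CohortSpec()
    rows = []
    for pair_id, cfg in generate_cohort(spec, seed=seed):
        if cfg.stg12 > 0:
            truth = "excitatory"
        elif cfg.stg12 < 0:
            truth = "inhibitory"
        else:
            truth = "none"
        pair = simulate_pair(cfg)
        cch = compute_cch(pair.s1, pair.s2)
        ach1 = compute_ach(pair.s1)
        ach2 = compute_ach(pair.s2)
        dcch = deconvolve_cch(cch, ach1, ach2).dcch
        for method in predictors:
            for deconv, histo in ((False, cch), (True, dcch)):
                pred = make_predictor(histo, method)
                est = estimate_stg(histo, method, roi_ms=roi_ms, sign="auto")
                det = detect_connection(histo, pred, roi_ms=roi_ms, alpha=alpha)
                rows.append(
                    {
                        "pair_id": pair_id, "method": method,
                        "deconvolved": deconv, "truth": truth,
                        "rstg": cfg.stg12, "br1": cfg.neuron1.br1,
                        "duration": cfg.duration,
                        "comod_sigma": cfg.comod_sigma,
                        "estg": est.estg, "label": det.label,
                        "p_exc": det.p_exc, "p_inh": det.p_inh,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["manifest"] = _manifest(
        "cohort_benchmark", spec=asdict(spec), seed=seed, alpha=alpha,
    )
    return df


def mse_table(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Mean squared eSTG error vs ground truth over connected pairs,
    per (method, deconvolved)."""
    conn = cohort_df[cohort_df["truth"] != "none"]
    err = (conn["estg"] - conn["rstg"]) ** 2
    return (
        conn.assign(sq_err=err)
        .groupby(["method", "deconvolved"])["sq_err"]
        .mean()
        .rename("mse")
        .reset_index()
    )


def f1_table(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Pooled f1 per (method, deconvolved)."""
    rows = []
    for (method, deconv), grp in cohort_df.groupby(["method", "deconvolved"]):
        cs = confusion_and_f1(grp["label"].tolist(), grp["truth"].tolist())
        rows.append(
            {
                "method": method, "deconvolved": deconv, "f1": cs.f1,
                "tp": cs.tp, "fp": cs.fp_exc + cs.fp_inh,
                "fn": cs.fn_exc + cs.fn_inh,
            }
        )
    return pd.DataFrame(rows)


def run_network_experiment(
    n_e: int = 20,
    n_i: int = 5,
    duration: float = 1200.0,
    seed: int = 0,
    lognormal: bool = False,
    alpha: float = 0.001,
    roi_ms=(0.0, 5.0),
) -> dict:
    """Simulate one conductance-based network and analyze every cell pair.

    Returns ``cells`` (per-cell class, BF, rate, burst index), ``pairs``
    (per ordered pair: truth, median-predictor eSTG and detection label
    with and without deconvolution), and the config.
    """
    cfg = build_network(
        n_e=n_e, n_i=n_i, seed=seed, lognormal=lognormal, duration=duration
    )
    trains = simulate_network(cfg)
    n = cfg.n_cells
    achs_50 = [
        compute_ach(tr, half_width_bins=50) if tr.n_spikes else None for tr in trains
    ]
    achs = [compute_ach(tr) if tr.n_spikes else None for tr in trains]
    cell_rows = []
    for c, tr in enumerate(trains):
        bi = np.nan
        if achs_50[c] is not None:
            try:
                bi = burst_index(achs_50[c]).burst_index
            except ValueError:
                pass
        cell_rows.append(
            {
                "cell": c, "cls": "E" if c < n_e else "I",
                "bf": cfg.v_reset[c] if c < n_e else np.nan,
                "rate": tr.rate, "burst_index": bi,
            }
        )
    truth = {(pre, post): sign for pre, post, sign, _ in cfg.edges()}
    pair_rows = []
    for pre in range(n):
        for post in range(n):
            if pre == post or not trains[pre].n_spikes or not trains[post].n_spikes:
                continue
            cch = compute_cch(trains[pre], trains[post])
            dcch = deconvolve_cch(cch, achs[pre], achs[post]).dcch
            row = {
                "pre": pre, "post": post,
                "pre_cls": "E" if pre < n_e else "I",
                "post_cls": "E" if post < n_e else "I",
                "truth": truth.get((pre, post), "none"),
                "g": cfg.adjacency[post, pre],
                "bf_pre": cfg.v_reset[pre] if pre < n_e else np.nan,
            }
            for tag, histo in (("raw", cch), ("dc", dcch)):
                pred = make_predictor(histo, "median")
                est = estimate_stg(histo, "median", roi_ms=roi_ms, sign="auto")
                det = detect_connection(histo, pred, roi_ms=roi_ms, alpha=alpha)
                row[f"estg_{tag}"] = est.estg
                row[f"label_{tag}"] = det.label
            pair_rows.append(row)
    pairs = pd.DataFrame(pair_rows)
    cells = pd.DataFrame(cell_rows)
    manifest = _manifest(
        "network_experiment", n_e=n_e, n_i=n_i, duration=duration, seed=seed,
        lognormal=lognormal, alpha=alpha,
    )
    pairs.attrs["manifest"] = manifest
    return {"cells": cells, "pairs": pairs, "config": cfg, "manifest": manifest}
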