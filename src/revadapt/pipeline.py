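"""End-to-end reverberation-adaptation analyses.

The functions here orchestrate the full study on synthetic data:

* fit dereverberation kernels per room and measure how their inhibitory
  temporal structure depends on reverberation;
* fit per-room STRFs to (simulated) neuronal responses and compare
  paired centre-of-mass / peak-time metrics across rooms (Wilcoxon
  signed-rank), including the three-room trend (Kruskal-Wallis with
  rank-based Fisher-LSD post hocs);
* build non-adaptive LNP (or NRF-Poisson) controls per unit and subtract
  their stimulus-statistics artefact from the measured room effects;
* analyse responses to anechoic noise probes, room-switching stimuli and
  cross-room response correlations.

Population tests are two-sided throughout and no multiple-comparison
correction is applied (each report says so).  Undefined metrics (NaN)
are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import synth
from .cochlea import CochlearConfig, Cochleagram, cochleagram
from .metrics import psth_com, rf_metrics
from .neurons import NRFConfig, fit_nrf, fit_sigmoid, sigmoid
from .ridge import (
    FitConfig,
    Kernel,
    build_lag_matrix,
    fit_dereverb,
    fit_ridge_cv_multi,
    mse_reduction,
)
from .room import measure_rt, simulate_preset

METRIC_COLUMNS = ("com_plus", "com_minus", "pt_plus", "pt_minus")


# ---------------------------------------------------------------------------
# Tables and paired statistics


def metrics_table(
    kernels_by_room: dict[str, list[Kernel]], tau_ms: float = 10.0
) -> pd.DataFrame:
    """Long-format table of temporal metrics: one row per (unit, room)."""
    rows = []
    for room_label, kernels in kernels_by_room.items():
        for k in kernels:
            m = rf_metrics(k, tau_ms)
            rows.append(
                {
                    "unit": k.target_id,
                    "room": room_label,
                    "com_plus": m.com_plus,
                    "com_minus": m.com_minus,
                    "pt_plus": m.pt_plus,
                    "pt_minus": m.pt_minus,
                    "best_frequency": m.best_frequency,
                }
            )
    return pd.DataFrame(rows)


def wilcoxon_summary(diffs: np.ndarray, min_pairs: int = 5) -> dict:
    """Median/mean and two-sided Wilcoxon signed-rank p of paired
    differences.  NaNs are dropped; all-zero differences give p = 1;
    fewer than min_pairs valid pairs skips the test (p = NaN)."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    out = {
        "n": int(d.size),
        "median": float(np.median(d)) if d.size else float("nan"),
        "mean": float(np.mean(d)) if d.size else float("nan"),
        "p": float("nan"),
    }
    if d.size < min_pairs:
        return out
    if np.all(d == 0):
        out["p"] = 1.0
        return out
    out["p"] = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
    return out


def paired_differences(
    table: pd.DataFrame, room_pair: tuple[str, str], metric: str
) -> pd.Series:
    """Per-unit metric difference room_pair[1] - room_pair[0]."""
    wide = table.pivot_table(index="unit", columns="room", values=metric, dropna=False)
    return wide[room_pair[1]] - wide[room_pair[0]]


def compare_rooms(
    table: pd.DataFrame,
    room_pair: tuple[str, str] = ("small", "large"),
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired room comparison of temporal metrics.

    Returns (summary, diffs): summary has one row per metric with the
    median/mean difference (room_pair[1] - room_pair[0]) and the
    two-sided Wilcoxon signed-rank p; diffs holds the per-unit
    differences behind each row.
    """
    diffs = pd.DataFrame(
        {m: paired_differences(table, room_pair, m) for m in metrics}
    )
    summary = pd.DataFrame(
        [{"metric": m, **wilcoxon_summary(diffs[m].to_numpy())} for m in metrics]
    )
    return summary, diffs


def fisher_lsd_ranks(
    groups: list[np.ndarray], h_statistic: float
) -> dict[tuple[int, int], float]:
    """Rank-based Fisher least-significant-difference post hocs
    (Conover-Iman) following a Kruskal-Wallis test."""
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    k = len(groups)
    ranks = stats.rankdata(pooled)
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    dof = n_total - k
    scale = s2 * (n_total - 1 - h_statistic) / dof
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
            t = (mean_ranks[i] - mean_ranks[j]) / se
            out[(i, j)] = float(2.0 * stats.t.sf(abs(t), dof))
    return out


def three_room_trend(
    table: pd.DataFrame,
    metric: str,
    rooms: tuple[str, ...] = ("small", "medium", "large"),
) -> dict:
    """Kruskal-Wallis across rooms plus pairwise rank-LSD post hocs."""
    groups = [
        table.loc[table["room"] == r, metric].dropna().to_numpy() for r in rooms
    ]
    if any(g.size < 2 for g in groups):
        raise ValueError("every room needs at least 2 valid values")
    h, p = stats.kruskal(*groups)
    pairwise = {
        (rooms[i], rooms[j]): pv
        for (i, j), pv in fisher_lsd_ranks(groups, h).items()
    }
    medians = {r: float(np.median(g)) for r, g in zip(rooms, groups)}
    return {"H": float(h), "p": float(p), "pairwise": pairwise, "medians": medians}


# ---------------------------------------------------------------------------
# Designs and response bookkeeping


def blocks_design(
    coch_blocks: list[Cochleagram], h_max: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stack per-block lagged design matrices (history never crosses a
    block boundary).  Returns (X, [(start, stop) per block])."""
    mats, ranges = [], []
    start = 0
    for c in coch_blocks:
        X = build_lag_matrix(c, h_max)
        mats.append(X)
        ranges.append((start, start + X.shape[0]))
        start += X.shape[0]
    return np.vstack(mats), ranges


def leading_rows(
    block_ranges: list[tuple[int, int]], keep_bins: int
) -> np.ndarray:
    """Row indices of the first keep_bins bins of every block (the
    probe-free portion used for STRF fitting)."""
    idx = [np.arange(a, min(a + keep_bins, b)) for a, b in block_ranges]
    return np.concatenate(idx)


def kernels_from_multi(
    W: np.ndarray,
    b: np.ndarray,
    lam: np.ndarray,
    n_freq: int,
    h_max: int,
    channel_centers: np.ndarray | None,
) -> list[Kernel]:
    return [
        Kernel(
            weights=W[i].reshape(n_freq, h_max),
            bias=float(b[i]),
            target_id=i,
            lam=float(lam[i]),
            channel_centers=channel_centers,
        )
        for i in range(W.shape[0])
    ]


# ---------------------------------------------------------------------------
# Non-adaptive control simulation (LNP / NRF-Poisson)


def control_comparison(
    design_by_room: dict[str, np.ndarray],
    counts_by_room: dict[str, np.ndarray],  # (n_units, n_trials, T)
    rows_by_room: dict[str, np.ndarray],
    real_kernels_by_room: dict[str, list[Kernel]],
    cfg: FitConfig,
    n_freq: int,
    channel_centers: np.ndarray | None = None,
    room_pair: tuple[str, str] = ("small", "large"),
    n_trials: int = 10,
    seed: int = 0,
    model: str = "lnp",
    nrf_cfg: NRFConfig | None = None,
) -> dict:
    """Fit per-unit non-adaptive simulations and compare their apparent
    room effects with the real ones.

    For each unit: (1) fit a single model on the rooms combined (STRF for
    'lnp', network receptive field for 'nrfp'); (2) for LNP, fit the
    output sigmoid on the joint prediction; (3) generate Poisson trials
    per room; (4) refit per-room STRFs from the simulated responses; and
    (5) subtract the simulated room differences from the real ones.
    A positive residual means the real shift exceeds what stimulus
    statistics alone produce in a non-adaptive neuron.

    Returns a dict with the real/simulated/residual difference tables,
    Wilcoxon summaries, the simulated trial counts (reusable for
    response-correlation analyses) and the simulated per-room kernels.
    """
    rooms = list(room_pair)
    mean_by_room = {r: counts_by_room[r].mean(axis=1) for r in rooms}
    n_units = mean_by_room[rooms[0]].shape[0]

    X_joint = np.vstack([design_by_room[r][rows_by_room[r]] for r in rooms])
    Y_joint = np.hstack([mean_by_room[r][:, rows_by_room[r]] for r in rooms])

    sim_rate_by_room: dict[str, np.ndarray] = {}
    if model == "lnp":
        W, b, _ = fit_ridge_cv_multi(X_joint, Y_joint.T, cfg)
        pred_joint = X_joint @ W.T + b  # (T_joint, n_units)
        nonlins = [
            fit_sigmoid(pred_joint[:, i], Y_joint[i]) for i in range(n_units)
        ]
        for r in rooms:
            drive = design_by_room[r] @ W.T + b
            sim_rate_by_room[r] = np.stack(
                [
                    np.clip(sigmoid(drive[:, i], nonlins[i]), 0.0, None)
                    for i in range(n_units)
                ]
            )
    elif model == "nrfp":
        nrf_cfg = nrf_cfg or NRFConfig(h_max=cfg.h_max)
        models = [
            fit_nrf(X_joint, Y_joint[i], nrf_cfg) for i in range(n_units)
        ]
        for r in rooms:
            sim_rate_by_room[r] = np.stack(
                [np.clip(m.predict(design_by_room[r]), 0.0, None) for m in models]
            )
    else:
        raise ValueError("model must be 'lnp' or 'nrfp'")

    root = np.random.SeedSequence(seed)
    room_seeds = dict(zip(rooms, root.spawn(len(rooms))))
    sim_counts_by_room = {}
    for r in rooms:
        rng = np.random.default_rng(room_seeds[r])
        rate = sim_rate_by_room[r]
        sim_counts_by_room[r] = rng.poisson(
            rate[:, None, :], size=(n_units, n_trials, rate.shape[1])
        )

    sim_kernels_by_room = {}
    for r in rooms:
        Wr, br, lamr = fit_ridge_cv_multi(
            design_by_room[r][rows_by_room[r]],
            sim_counts_by_room[r].mean(axis=1)[:, rows_by_room[r]].T,
            cfg,
        )
        sim_kernels_by_room[r] = kernels_from_multi(
            Wr, br, lamr, n_freq, cfg.h_max, channel_centers
        )

    real_table = metrics_table({r: real_kernels_by_room[r] for r in rooms})
    sim_table = metrics_table(sim_kernels_by_room)
    real_sum, real_diffs = compare_rooms(real_table, room_pair)
    sim_sum, sim_diffs = compare_rooms(sim_table, room_pair)
    residual = real_diffs - sim_diffs
    residual_summary = pd.DataFrame(
        [
            {"metric": m, **wilcoxon_summary(residual[m].to_numpy())}
            for m in METRIC_COLUMNS
        ]
    )
    return {
        "real_summary": real_sum,
        "sim_summary": sim_sum,
        "residual_summary": residual_summary,
        "real_diffs": real_diffs,
        "sim_diffs": sim_diffs,
        "residual_diffs": residual,
        "sim_counts_by_room": sim_counts_by_room,
        "sim_kernels_by_room": sim_kernels_by_room,
        "model": model,
    }


# ---------------------------------------------------------------------------
# Probe, switching and invariance analyses


def probe_analysis(
    counts_by_room: dict[str, list[np.ndarray]],  # per block: (U, repeats, T)
    logs_by_room: dict[str, synth.ProbeLog],
    bin_s: float,
    window_ms: tuple[float, float] = (0.0, 100.0),
    room_pair: tuple[str, str] = ("small", "large"),
) -> dict:
    """Probe-aligned PSTH centre-of-mass comparison across rooms.

    PSTHs pool all probed repeats of all blocks of a room; unprobed
    repeats are excluded.  The centre of mass of each unit's mean rate in
    the post-onset window is compared across rooms (paired Wilcoxon).
    """
    n_win = int(round(window_ms[1] / 1000.0 / bin_s))
    psths = {}
    for room_label in room_pair:
        blocks = counts_by_room[room_label]
        log = logs_by_room[room_label]
        n_units = blocks[0].shape[0]
        acc = np.zeros((n_units, n_win))
        count = 0
        for b, counts in enumerate(blocks):
            for r in range(counts.shape[1]):
                onset = log.onsets.get((b, r))
                if onset is None:
                    continue
                i0 = int(round(onset / bin_s))
                seg = counts[:, r, i0 : i0 + n_win]
                if seg.shape[1] < n_win:
                    continue
                acc += seg
                count += 1
        if count == 0:
            raise ValueError(f"no probed repeats found for room {room_label!r}")
        psths[room_label] = acc / count

    tau_ms = bin_s * 1000.0
    com = {
        r: np.array([psth_com(p, tau_ms, window_ms) for p in psths[r]])
        for r in room_pair
    }
    diffs = com[room_pair[1]] - com[room_pair[0]]
    return {
        "psth_by_room": psths,
        "com_by_room": com,
        "diffs": diffs,
        "summary": wilcoxon_summary(diffs),
    }


def switching_analysis(
    designs: list[np.ndarray],  # per stimulus (T, P)
    responses: np.ndarray,  # (U, n_stimuli, T) trial-averaged counts
    annotations: list[list[dict]],
    bin_s: float,
    cfg: FitConfig,
    n_freq: int,
    channel_centers: np.ndarray | None = None,
    exclude_first_s: float = 8.0,
    exclude_period_start_s: float = 0.5,
) -> dict:
    """Fit separate STRFs to the S1/S2/L1/L2 switching periods and test
    for within-epoch adaptation (S2 - S1 and L2 - L1 shifts).

    The first exclude_first_s of each stimulus (the first epoch, which
    has no preceding room context) and the first exclude_period_start_s
    of every period (transition response) are excluded from fitting.
    """
    labels = ("S1", "S2", "L1", "L2")
    rows_by_label = {lab: [] for lab in labels}
    X_by_label = {lab: [] for lab in labels}
    Y_by_label = {lab: [] for lab in labels}
    for s, (X, ann) in enumerate(zip(designs, annotations)):
        T = X.shape[0]
        times = (np.arange(T) + 0.5) * bin_s
        for period in ann:
            if period["end"] <= exclude_first_s:
                continue
            lo = period["start"] + exclude_period_start_s
            hi = period["end"]
            rows = np.nonzero((times >= lo) & (times < hi))[0]
            X_by_label[period["label"]].append(X[rows])
            Y_by_label[period["label"]].append(responses[:, s, rows])
            rows_by_label[period["label"]].append((s, rows))
    kernels_by_label = {}
    for lab in labels:
        if not X_by_label[lab]:
            raise ValueError(f"no usable rows for period {lab}")
        Xl = np.vstack(X_by_label[lab])
        Yl = np.hstack(Y_by_label[lab])
        W, b, lam = fit_ridge_cv_multi(Xl, Yl.T, cfg)
        kernels_by_label[lab] = kernels_from_multi(
            W, b, lam, n_freq, cfg.h_max, channel_centers
        )
    table = metrics_table(kernels_by_label)
    out = {"kernels_by_label": kernels_by_label, "table": table}
    for pair_name, pair in (("S2-S1", ("S1", "S2")), ("L2-L1", ("L1", "L2"))):
        summary, diffs = compare_rooms(table, pair, metrics=("com_plus", "com_minus"))
        out[pair_name] = {"summary": summary, "diffs": diffs}
    return out


def invariance_correlation(
    real_by_room: dict[str, np.ndarray],  # (U, trials, T)
    sim_by_room: dict[str, np.ndarray],
    room_pair: tuple[str, str],
) -> dict:
    """Cross-room Pearson correlation of trial-averaged responses,
    real vs simulated (per unit), with a Wilcoxon on the difference.

    A positive median CC(real) - CC(sim) means the real responses are
    more reverberation-invariant than their non-adaptive simulations.
    """

    def unit_ccs(by_room) -> np.ndarray:
        a = by_room[room_pair[0]].mean(axis=1)
        b = by_room[room_pair[1]].mean(axis=1)
        ccs = np.full(a.shape[0], np.nan)
        for i in range(a.shape[0]):
            if a[i].std() > 0 and b[i].std() > 0:
                ccs[i] = np.corrcoef(a[i], b[i])[0, 1]
        return ccs

    cc_real = unit_ccs(real_by_room)
    cc_sim = unit_ccs(sim_by_room)
    diffs = cc_real - cc_sim
    return {
        "cc_real": cc_real,
        "cc_sim": cc_sim,
        "diffs": diffs,
        "summary": wilcoxon_summary(diffs),
    }


def frequency_dependence(
    table: pd.DataFrame,
    rooms: tuple[str, ...],
    rt_profiles: dict | None = None,
) -> dict:
    """Pearson correlation of COM+- with (log) best frequency per room,
    and of RT60 with (log) band frequency for each supplied RT profile."""
    out: dict = {"com_vs_bf": {}, "rt_vs_freq": {}}
    for room_label in rooms:
        sub = table[table["room"] == room_label]
        for metric in ("com_plus", "com_minus"):
            x = np.log2(sub["best_frequency"].to_numpy(dtype=float))
            y = sub[metric].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() >= 3 and np.ptp(x[keep]) > 0 and np.ptp(y[keep]) > 0:
                r, p = stats.pearsonr(x[keep], y[keep])
                slope, intercept = np.polyfit(x[keep], y[keep], 1)
            else:
                r = p = slope = intercept = float("nan")
            out["com_vs_bf"][(room_label, metric)] = {
                "r": float(r),
                "p": float(p),
                "slope": float(slope),
                "intercept": float(intercept),
                "n": int(keep.sum()),
            }
    if rt_profiles:
        for room_label, prof in rt_profiles.items():
            keep = np.isfinite(prof.rt60)
            r, p = stats.pearsonr(
                np.log2(prof.band_centers[keep]), prof.rt60[keep]
            )
            out["rt_vs_freq"][room_label] = {"r": float(r), "p": float(p)}
    return out


# ---------------------------------------------------------------------------
# Experiment runners (the study, end to end, on synthetic data)


@dataclass
class ExperimentConfig:
    """Scales and settings shared by the end-to-end runners."""

    sample_rate: float = 48828.0
    coch: CochlearConfig = None  # type: ignore[assignment]
    fit: FitConfig = None  # type: ignore[assignment]
    block_duration: float = 40.0
    n_blocks: int = 2
    fit_seconds: float = 36.0  # leading probe-free seconds of each block
    n_trials: int = 10
    rooms: tuple[str, ...] = ("small", "large")

    def __post_init__(self) -> None:
        if self.coch is None:
            self.coch = CochlearConfig()
        if self.fit is None:
            self.fit = FitConfig()


def _room_irs(cfg: ExperimentConfig, include_anechoic: bool = False) -> dict:
    rooms = list(cfg.rooms) + (["anechoic"] if include_anechoic else [])
    irs = {}
    for r in rooms:
        _, _, ir = simulate_preset(r, cfg.sample_rate)
        irs[r] = ir
    return irs


def room_ranks_from_rt(irs: dict, coch_cfg: CochlearConfig) -> dict[str, float]:
    """Rank rooms (0, 1, 2, ...) by their median RT60."""
    medians = {r: measure_rt(ir, coch_cfg).median_rt60 for r, ir in irs.items()}
    ordered = sorted(medians, key=medians.get)
    return {r: float(i) for i, r in enumerate(ordered)}


def _room_cochleagrams(
    blocks: list[np.ndarray], irs: dict, cfg: ExperimentConfig
) -> dict[str, list[Cochleagram]]:
    rendered = synth.render_rooms(blocks, irs, cfg.sample_rate)
    return {
        room_label: [cochleagram(b, cfg.sample_rate, cfg.coch) for b in waves]
        for room_label, waves in rendered.items()
    }


def run_rt_experiment(
    sample_rate: float = 48828.0,
    rooms: tuple[str, ...] = ("small", "medium", "large"),
    coch_cfg: CochlearConfig | None = None,
) -> dict:
    """Simulate the study rooms and measure their per-band RT60/RT10."""
    coch_cfg = coch_cfg or CochlearConfig()
    profiles = {}
    for r in rooms:
        _, _, ir = simulate_preset(r, sample_rate)
        profiles[r] = measure_rt(ir, coch_cfg)
    rows = [
        {
            "room": r,
            "median_rt60_s": p.median_rt60,
            "median_rt10_s": p.median_rt10,
            "n_valid_bands": int(np.sum(p.valid)),
        }
        for r, p in profiles.items()
    ]
    return {"profiles": profiles, "summary": pd.DataFrame(rows)}


def run_dereverb_experiment(
    seed: int = 0,
    cfg: ExperimentConfig | None = None,
    train_blocks: int = 4,
    test_blocks: int = 1,
) -> dict:
    """Train the normative dereverberation model per room and analyse it.

    Generates a training and a held-out test corpus, renders both in each
    room (and anechoically), fits the per-channel kernels on the training
    renders and evaluates the held-out MSE reduction; then compares the
    kernels' inhibitory/excitatory temporal metrics across rooms.
    """
    cfg = cfg or ExperimentConfig()
    root = np.random.SeedSequence(seed)
    s_train, s_test = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(2)]
    corpus_kwargs = dict(
        snippet_duration=2.0,
        block_duration=cfg.block_duration,
        sample_rate=cfg.sample_rate,
    )
    per_block = int(cfg.block_duration / 2.0)
    train = synth.generate_corpus(
        synth.CorpusConfig(
            n_snippets=train_blocks * per_block, seed=s_train, **corpus_kwargs
        )
    )
    test = synth.generate_corpus(
        synth.CorpusConfig(
            n_snippets=test_blocks * per_block, seed=s_test, **corpus_kwargs
        )
    )
    irs = _room_irs(cfg, include_anechoic=True)
    coch_train = _room_cochleagrams(train.blocks, irs, cfg)
    coch_test = _room_cochleagrams(test.blocks, irs, cfg)

    def concat(coch_list: list[Cochleagram]) -> Cochleagram:
        return Cochleagram(
            values=np.hstack([c.values for c in coch_list]),
            channel_centers=coch_list[0].channel_centers,
            bin_duration=coch_list[0].bin_duration,
            floor_db=coch_list[0].floor_db,
        )

    models, reductions, kernels_by_room = {}, {}, {}
    for r in cfg.rooms:
        model = fit_dereverb(
            concat(coch_train[r]), concat(coch_train["anechoic"]), cfg.fit
        )
        model.room_label = r
        models[r] = model
        reductions[r] = mse_reduction(
            model, concat(coch_test[r]), concat(coch_test["anechoic"])
        )
        kernels_by_room[r] = model.kernels

    table = metrics_table(kernels_by_room)
    # a dereverberation kernel's "frequency" is its output channel
    centers = coch_train[cfg.rooms[0]][0].channel_centers
    table["best_frequency"] = table["unit"].map(lambda i: centers[int(i)])
    summary, diffs = compare_rooms(table, (cfg.rooms[0], cfg.rooms[-1]))
    freq = frequency_dependence(table, cfg.rooms)
    return {
        "models": models,
        "mse_reduction": reductions,
        "table": table,
        "summary": summary,
        "diffs": diffs,
        "frequency_dependence": freq,
    }


def run_population_experiment(
    seed: int = 0,
    cfg: ExperimentConfig | None = None,
    n_units: int = 100,
    adaptation_shift_ms: float = 10.0,
    pop_cfg: synth.PopulationConfig | None = None,
    run_control: bool = True,
    control_model: str = "lnp",
) -> dict:
    """Simulate a ground-truth population and run the full STRF pipeline.

    Returns per-room STRFs and metric tables for an adaptive population
    (planted inhibition-delay shift) and a static one (shift 0), the
    paired room comparisons, and optionally the non-adaptive LNP control
    comparison plus cross-room response correlations.
    """
    cfg = cfg or ExperimentConfig()
    pop_cfg = pop_cfg or synth.PopulationConfig(
        n_freq=cfg.coch.n_channels, h_max=cfg.fit.h_max
    )
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(6)]
    s_corpus, s_pop_a, s_pop_s, s_sim, s_ctrl_a, s_ctrl_s = seeds

    corpus = synth.generate_corpus(
        synth.CorpusConfig(
            n_snippets=cfg.n_blocks * int(cfg.block_duration / 2.0),
            block_duration=cfg.block_duration,
            sample_rate=cfg.sample_rate,
            seed=s_corpus,
        )
    )
    irs = _room_irs(cfg)
    ranks = room_ranks_from_rt(irs, cfg.coch)
    coch_by_room = _room_cochleagrams(corpus.blocks, irs, cfg)

    design_by_room, rows_by_room = {}, {}
    keep_bins = int(round(cfg.fit_seconds * 1000.0 / cfg.coch.hop_ms))
    for r in cfg.rooms:
        X, ranges = blocks_design(coch_by_room[r], cfg.fit.h_max)
        design_by_room[r] = X
        rows_by_room[r] = leading_rows(ranges, keep_bins)

    populations = {
        "adaptive": synth.generate_population(
            n_units, adaptation_shift_ms, pop_cfg, seed=s_pop_a
        ),
        "static": synth.generate_population(n_units, 0.0, pop_cfg, seed=s_pop_s),
    }
    centers = coch_by_room[cfg.rooms[0]][0].channel_centers
    out: dict = {"room_ranks": ranks, "populations": populations}
    for name, neurons in populations.items():
        counts_by_room = synth.simulate_population(
            neurons,
            design_by_room,
            ranks,
            n_trials=cfg.n_trials,
            seed=s_sim + (0 if name == "adaptive" else 1),
        )
        kernels_by_room = {}
        for r in cfg.rooms:
            W, b, lam = fit_ridge_cv_multi(
                design_by_room[r][rows_by_room[r]],
                counts_by_room[r].mean(axis=1)[:, rows_by_room[r]].T,
                cfg.fit,
            )
            kernels_by_room[r] = kernels_from_multi(
                W, b, lam, cfg.coch.n_channels, cfg.fit.h_max, centers
            )
        table = metrics_table(kernels_by_room)
        summary, diffs = compare_rooms(table, (cfg.rooms[0], cfg.rooms[-1]))
        entry = {
            "counts_by_room": counts_by_room,
            "kernels_by_room": kernels_by_room,
            "table": table,
            "summary": summary,
            "diffs": diffs,
        }
        if run_control:
            entry["control"] = control_comparison(
                design_by_room,
                counts_by_room,
                rows_by_room,
                kernels_by_room,
                cfg.fit,
                cfg.coch.n_channels,
                channel_centers=centers,
                room_pair=(cfg.rooms[0], cfg.rooms[-1]),
                n_trials=cfg.n_trials,
                seed=s_ctrl_a if name == "adaptive" else s_ctrl_s,
                model=control_model,
            )
            entry["invariance"] = invariance_correlation(
                counts_by_room,
                entry["control"]["sim_counts_by_room"],
                (cfg.rooms[0], cfg.rooms[-1]),
            )
        out[name] = entry
    return out


def _adaptation_rank_schedule(
    annotations: list[dict],
    room_rank: dict[str, float],
    tau_s: float,
    initial_rank: float = 0.5,
) -> list[float]:
    """Mean effective reverberation rank per switching period.

    After each room switch the effective rank relaxes exponentially
    toward the new room's rank with time constant tau_s; each period is
    assigned its time-averaged rank.  Models gradual adaptation; a static
    population ignores the schedule entirely.
    """
    state = initial_rank
    means = []
    for period in annotations:
        target = room_rank["large" if period["label"].startswith("L") else "small"]
        duration = period["end"] - period["start"]
        if tau_s <= 0:
            means.append(target)
            state = target
            continue
        decay = np.exp(-duration / tau_s)
        mean_rank = target + (state - target) * (tau_s / duration) * (1.0 - decay)
        state = target + (state - target) * decay
        means.append(mean_rank)
    return means


def run_probe_experiment(
    seed: int = 0,
    cfg: ExperimentConfig | None = None,
    n_units: int = 60,
    adaptation_shift_ms: float = 10.0,
    pop_cfg: synth.PopulationConfig | None = None,
    probe_spec: synth.ProbeSpec | None = None,
) -> dict:
    """Noise-probe study: embed unreverberated bursts late in each block,
    simulate per-repeat responses of a ground-truth population, and
    compare probe-aligned PSTH centres of mass across rooms.

    Probed repeats see a different cochleagram than unprobed ones (the
    probe is added to the rendered waveform), so each repeat is one
    Poisson draw from its own rate series.
    """
    cfg = cfg or ExperimentConfig()
    pop_cfg = pop_cfg or synth.PopulationConfig(
        n_freq=cfg.coch.n_channels, h_max=cfg.fit.h_max
    )
    probe_spec = probe_spec or synth.ProbeSpec()
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(4)]
    s_corpus, s_pop, s_probe, s_noise = seeds

    corpus = synth.generate_corpus(
        synth.CorpusConfig(
            n_snippets=cfg.n_blocks * int(cfg.block_duration / 2.0),
            block_duration=cfg.block_duration,
            sample_rate=cfg.sample_rate,
            seed=s_corpus,
        )
    )
    irs = _room_irs(cfg)
    ranks = room_ranks_from_rt(irs, cfg.coch)
    rendered = synth.render_rooms(corpus.blocks, irs, cfg.sample_rate)
    neurons = synth.generate_population(
        n_units, adaptation_shift_ms, pop_cfg, seed=s_pop
    )

    # condition-independent drive normalisation (probe-free stimuli)
    ref_design = np.vstack(
        [
            build_lag_matrix(cochleagram(w, cfg.sample_rate, cfg.coch), cfg.fit.h_max)
            for r in cfg.rooms
            for w in rendered[r]
        ]
    )
    W0 = np.stack([n.kernel(0.0).weights.ravel() for n in neurons], axis=1)
    ref_drive = ref_design @ W0
    mu, sd = ref_drive.mean(axis=0), ref_drive.std(axis=0)
    sd[sd == 0] = 1.0

    rng = np.random.default_rng(s_noise)
    counts_by_room: dict[str, list[np.ndarray]] = {}
    logs_by_room: dict[str, synth.ProbeLog] = {}
    for room_label in cfg.rooms:
        log = synth.make_probe_log(
            len(rendered[room_label]),
            cfg.block_duration,
            probe_spec,
            cfg.sample_rate,
            seed=s_probe + hash(room_label) % 1000,
        )
        logs_by_room[room_label] = log
        Wr = np.stack(
            [n.kernel(ranks[room_label]).weights.ravel() for n in neurons], axis=1
        )
        blocks_counts = []
        for b, block_wave in enumerate(rendered[room_label]):
            # unprobed repeats share one rate series
            base_design = build_lag_matrix(
                cochleagram(block_wave, cfg.sample_rate, cfg.coch), cfg.fit.h_max
            )
            T = base_design.shape[0]
            counts = np.zeros((n_units, probe_spec.n_repeats, T), dtype=np.int64)
            base_z = (base_design @ Wr - mu) / sd
            for r in range(probe_spec.n_repeats):
                if log.onsets[(b, r)] is None:
                    z = base_z
                else:
                    wave = synth.apply_probe(
                        block_wave, log, b, r, cfg.sample_rate
                    )
                    design = build_lag_matrix(
                        cochleagram(wave, cfg.sample_rate, cfg.coch), cfg.fit.h_max
                    )
                    z = (design @ Wr - mu) / sd
                for i, nrn in enumerate(neurons):
                    rate = np.clip(sigmoid(z[:, i], nrn.nonlinearity), 0.0, None)
                    counts[i, r] = rng.poisson(rate)
            blocks_counts.append(counts)
        counts_by_room[room_label] = blocks_counts

    bin_s = cfg.coch.hop_ms / 1000.0
    analysis = probe_analysis(
        counts_by_room, logs_by_room, bin_s, room_pair=tuple(cfg.rooms)
    )
    analysis["room_ranks"] = ranks
    analysis["logs_by_room"] = logs_by_room
    return analysis


def run_switching_experiment(
    seed: int = 0,
    cfg: ExperimentConfig | None = None,
    n_units: int = 60,
    adaptation_shift_ms: float = 10.0,
    adaptation_tau_s: float = 3.0,
    pop_cfg: synth.PopulationConfig | None = None,
    spec: synth.SwitchingSpec | None = None,
) -> dict:
    """Room-switching study: build alternating small/large stimuli, let
    the population's inhibition delay relax toward each room's state with
    a time constant, fit period-wise STRFs (S1/S2/L1/L2) and test the
    within-epoch shifts.

    With adaptation_tau_s > 0 an adaptive population's inhibitory centre
    of mass should fall from S1 to S2 and rise from L1 to L2; a static
    population (shift 0) shows neither.
    """
    cfg = cfg or ExperimentConfig()
    pop_cfg = pop_cfg or synth.PopulationConfig(
        n_freq=cfg.coch.n_channels, h_max=cfg.fit.h_max
    )
    spec = spec or synth.SwitchingSpec()
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(4)]
    s_corpus, s_pop, s_switch, s_noise = seeds

    corpus = synth.generate_corpus(
        synth.CorpusConfig(
            n_snippets=cfg.n_blocks * int(cfg.block_duration / 2.0),
            block_duration=cfg.block_duration,
            sample_rate=cfg.sample_rate,
            seed=s_corpus,
        )
    )
    irs = _room_irs(cfg)
    ranks = room_ranks_from_rt(irs, cfg.coch)
    rendered = synth.render_rooms(corpus.blocks, irs, cfg.sample_rate)
    sw = synth.build_switching(
        rendered[cfg.rooms[0]], rendered[cfg.rooms[-1]], spec, cfg.sample_rate, seed=s_switch
    )
    neurons = synth.generate_population(
        n_units, adaptation_shift_ms, pop_cfg, seed=s_pop
    )

    designs = [
        build_lag_matrix(cochleagram(w, cfg.sample_rate, cfg.coch), cfg.fit.h_max)
        for w in sw.waveforms
    ]
    ref = np.vstack(designs)
    W0 = np.stack([n.kernel(0.0).weights.ravel() for n in neurons], axis=1)
    drive = ref @ W0
    mu, sd = drive.mean(axis=0), drive.std(axis=0)
    sd[sd == 0] = 1.0

    room_rank = {"small": ranks[cfg.rooms[0]], "large": ranks[cfg.rooms[-1]]}
    rng = np.random.default_rng(s_noise)
    bin_s = cfg.coch.hop_ms / 1000.0
    responses = np.zeros((n_units, len(designs), designs[0].shape[0]))
    for s_i, (X, ann) in enumerate(zip(designs, sw.annotations)):
        T = X.shape[0]
        times = (np.arange(T) + 0.5) * bin_s
        mean_ranks = _adaptation_rank_schedule(ann, room_rank, adaptation_tau_s)
        for period, rank_eff in zip(ann, mean_ranks):
            rows = (times >= period["start"]) & (times < period["end"])
            if not rows.any():
                continue
            Wp = np.stack(
                [n.kernel(rank_eff).weights.ravel() for n in neurons], axis=1
            )
            z = (X[rows] @ Wp - mu) / sd
            for i, nrn in enumerate(neurons):
                rate = np.clip(sigmoid(z[:, i], nrn.nonlinearity), 0.0, None)
                responses[i, s_i, rows] = rng.poisson(
                    rate, size=(cfg.n_trials, rate.size)
                ).mean(axis=0)

    analysis = switching_analysis(
        designs,
        responses,
        sw.annotations,
        bin_s,
        cfg.fit,
        n_freq=cfg.coch.n_channels,
        channel_centers=cfg.coch.channel_centers,
        exclude_first_s=spec.epoch,
    )
    analysis["room_ranks"] = ranks
    return analysis
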