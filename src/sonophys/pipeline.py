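"""End-to-end scenario orchestration: simulate cohorts, QC, detect, rate,
normalize, summarize, and run the group statistics, with reproducible reports.

A scenario mirrors one experiment design:

* ``repetitive_pw`` / ``repetitive_cw`` — network activity recorded in
  current clamp around a ~3-min train of repeated stimuli; per-cell spike
  rates are KDE-estimated, normalized to the 5-min pre-stimulation mean, and
  the post/pre interval means of a treated cohort are compared against an
  unstimulated control cohort with the Steel test.
* ``single_shot_pw`` / ``single_shot_cw`` — five 2-s stimuli at 20-s
  intervals; 2-s pre/stim/post interval means are averaged across repeats
  per cell and compared with the Friedman test.
* ``tonic_measurement`` — voltage-clamp recordings with a GABA_A blocker
  applied; tonic current amplitudes of treated vs control cohorts are
  compared with the Steel test.

Each cell owns a deterministic sub-seed spawned from the scenario seed, so
results are independent of execution order and repeat runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ConfigurationError, EventList, InvalidParameterError
from .detect import DetectorConfig, QCLimits, detect_spikes, qc_trace
from .dosimetry import StimProtocol
from .rates import interval_mean_frequency, kde_rate, normalize_rate
from .simulate import simulate_cc_trace, simulate_tonic_block_experiment
from .stats import StatResult, rank_test, steel_test
from .tonic import tonic_current_amplitude

__all__ = ["ScenarioConfig", "Report", "run_scenario"]

SCENARIOS = ("single_shot_pw", "single_shot_cw", "repetitive_pw",
             "repetitive_cw", "tonic_measurement")


def _default_protocol(scenario: str) -> StimProtocol:
    if scenario.endswith("_cw"):
        n_trains = 20 if scenario.startswith("repetitive") else 1
        return StimProtocol(mode="CW", tone_burst_duration=None, prf=None,
                            train_duration=0.1, n_trains=n_trains,
                            inter_train_onset_interval=10.0 if n_trains > 1 else 0.0)
    if scenario.startswith("repetitive"):
        return StimProtocol(n_trains=20, inter_train_onset_interval=10.0)
    return StimProtocol()


@dataclass
class ScenarioConfig:
    """Declarative description of one simulated experiment.

    Defaults mirror the modeled study: 19 treated vs 25 control cells for the
    repetitive scenario, a 192-s train of twenty 2-s pulsed-wave stimuli,
    5-min pre/post recording, 2-min comparison windows, a true post/pre
    suppression to 0.5, and a 20 pA tonic current revealed by the blocker.
    """

    scenario: str = "repetitive_pw"
    seed: int = 0
    n_cells: int = 19
    n_control: int = 25
    protocol: Optional[StimProtocol] = None

    # current-clamp network simulation
    sampling_rate: float = 2000.0
    pre_s: float = 300.0
    post_s: float = 300.0
    burst_rate: float = 0.25
    spikes_per_burst_mean: float = 8.0
    intraburst_isi: float = 0.02
    cc_noise_sd: float = 1.0
    suppression_ratio: float = 0.5

    # single-shot repeats
    n_repeats: int = 5
    repeat_interval_s: float = 20.0
    single_window_s: float = 2.0

    # analysis
    compare_window_s: float = 120.0
    grid_step: float = 0.01
    kernel_width: float = 0.5
    spike_threshold_mv: float = 0.0

    # tonic-measurement scenario
    tonic_pre_s: float = 10.0
    tonic_post_s: float = 10.0
    tonic_amplitude_pa: float = 20.0
    control_tonic_pa: float = 5.0
    mipsc_rate: float = 10.0
    vc_noise_sd: float = 3.0
    vc_sampling_rate: float = 10_000.0

    stats_n_draws: int = 100_000

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.protocol is None:
            self.protocol = _default_protocol(self.scenario)
        if not (0 < self.suppression_ratio <= 1):
            raise ConfigurationError("suppression_ratio must be in (0, 1]")
        if self.scenario.startswith("repetitive") and self.pre_s < 300.0:
            raise ConfigurationError(
                "repetitive scenarios need >= 300 s pre-stimulation for the "
                "5-min normalization baseline")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        proto = d.get("protocol")
        if isinstance(proto, dict):
            d["protocol"] = StimProtocol(**proto)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True) + "|" + __version__
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Per-cell tables, group statistics, and provenance for one scenario."""

    cells: pd.DataFrame
    stats: pd.DataFrame
    config: dict
    provenance: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False, float_format="%.12g")
        self.stats.to_csv(out / "stats.csv", index=False, float_format="%.12g")
        with (out / "report.json").open("w") as fh:
            json.dump({"config": self.config, "provenance": self.provenance},
                      fh, sort_keys=True, indent=2, default=str)
            fh.write("\n")

    def summary(self) -> str:
        lines = [f"Scenario: {self.config['scenario']} "
                 f"(seed {self.provenance['seed']}, hash {self.provenance['config_hash']})",
                 f"Cells analysed: {len(self.cells)}", "", "Group statistics:"]
        for _, row in self.stats.iterrows():
            lines.append(f"  {row['test']:>18s}  {row['comparison_label']:<28s} "
                         f"stat={row['statistic']:8.3f}  p={row['p_value']:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------

def _cell_seeds(seed: int, n: int) -> List[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _stats_frame(results: List[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "test": r.test, "comparison_label": r.comparison_label,
        "statistic": r.statistic, "p_value": r.p_value,
        "n_per_group": "/".join(map(str, r.n_per_group)),
        "adjusted": r.adjusted, "degenerate": r.degenerate,
        "method": r.method, "seed": r.seed,
    } for r in results])


def _analyze_network_cell(cfg: ScenarioConfig, cohort: str, cell: int, seed: int,
                          suppression: float) -> dict:
    stim_len = cfg.protocol.total_protocol_duration
    duration = cfg.pre_s + stim_len + cfg.post_s
    epoch = (cfg.pre_s, cfg.pre_s + stim_len)
    trace, truth = simulate_cc_trace(
        duration, cfg.burst_rate,
        spikes_per_burst=("poisson", cfg.spikes_per_burst_mean),
        intraburst_isi=cfg.intraburst_isi,
        stim_epoch=epoch,
        suppression_ratio=suppression,
        noise_sd=cfg.cc_noise_sd,
        sampling_rate=cfg.sampling_rate,
        seed=seed,
    )
    qc = qc_trace(trace, stim_epoch=epoch)
    det = DetectorConfig(spike_threshold_mv=cfg.spike_threshold_mv)
    events = detect_spikes(trace, det)
    rate = kde_rate(events, grid_step=cfg.grid_step, kernel_width=cfg.kernel_width,
                    t_start=0.0, t_stop=duration)
    norm = normalize_rate(rate, "repetitive", stim_onset=cfg.pre_s)
    w = cfg.compare_window_s
    windows = [("pre", cfg.pre_s - w, cfg.pre_s),
               ("stim", epoch[0], epoch[1]),
               ("post", duration - w, duration)]
    means = {s.label: s.mean_frequency for s in interval_mean_frequency(events, windows)}
    norm_means = {f"norm_{label}": norm.mean_in(a, b) for label, a, b in windows}
    return {
        "cohort": cohort, "cell": cell, "seed": seed,
        "qc_accepted": qc.accepted, "qc_reason": qc.reason.value,
        "n_spikes": len(events), "true_suppression": truth.suppression_ratio,
        **{f"freq_{k}_hz": v for k, v in means.items()},
        **norm_means,
    }


def _run_repetitive(cfg: ScenarioConfig) -> Report:
    seeds = _cell_seeds(cfg.seed, cfg.n_cells + cfg.n_control)
    suppression = cfg.suppression_ratio if cfg.scenario == "repetitive_pw" else 1.0
    rows = []
    for i in range(cfg.n_cells):
        rows.append(_analyze_network_cell(cfg, "treated", i, seeds[i], suppression))
    for i in range(cfg.n_control):
        rows.append(_analyze_network_cell(cfg, "control", i, seeds[cfg.n_cells + i], 1.0))
    cells = pd.DataFrame(rows)
    ok = cells[cells.qc_accepted]
    treated = ok[ok.cohort == "treated"]["norm_post"].to_numpy()
    control = ok[ok.cohort == "control"]["norm_post"].to_numpy()
    results = steel_test(control, [treated], method="mc",
                         n_draws=cfg.stats_n_draws, seed=cfg.seed)
    results += [rank_test("mann_whitney_u", [control, treated])]
    return cells, results


def _run_single_shot(cfg: ScenarioConfig) -> Report:
    seeds = _cell_seeds(cfg.seed, cfg.n_cells)
    w = cfg.single_window_s
    stim_len = cfg.protocol.total_protocol_duration
    duration = cfg.pre_s + cfg.n_repeats * cfg.repeat_interval_s
    rows = []
    for i in range(cfg.n_cells):
        trace, _ = simulate_cc_trace(
            duration, cfg.burst_rate,
            spikes_per_burst=("poisson", cfg.spikes_per_burst_mean),
            intraburst_isi=cfg.intraburst_isi,
            stim_epoch=None, suppression_ratio=1.0,
            noise_sd=cfg.cc_noise_sd, sampling_rate=cfg.sampling_rate,
            seed=seeds[i],
        )
        qc = qc_trace(trace)
        events = detect_spikes(trace, DetectorConfig(spike_threshold_mv=cfg.spike_threshold_mv))
        per_label = {"pre": [], "stim": [], "post": []}
        for k in range(cfg.n_repeats):
            onset = cfg.pre_s + k * cfg.repeat_interval_s
            windows = [("pre", onset - w, onset),
                       ("stim", onset, onset + stim_len),
                       ("post", onset + stim_len, onset + stim_len + w)]
            for s in interval_mean_frequency(events, windows):
                per_label[s.label].append(s.mean_frequency)
        rows.append({
            "cohort": "single_shot", "cell": i, "seed": seeds[i],
            "qc_accepted": qc.accepted, "qc_reason": qc.reason.value,
            "n_spikes": len(events),
            **{f"freq_{k}_hz": float(np.mean(v)) for k, v in per_label.items()},
        })
    cells = pd.DataFrame(rows)
    ok = cells[cells.qc_accepted]
    results = [rank_test("friedman", [ok["freq_pre_hz"].to_numpy(),
                                      ok["freq_stim_hz"].to_numpy(),
                                      ok["freq_post_hz"].to_numpy()])]
    results[0].comparison_label = "pre_vs_stim_vs_post"
    return cells, results


def _run_tonic(cfg: ScenarioConfig) -> Report:
    seeds = _cell_seeds(cfg.seed, cfg.n_cells + cfg.n_control)
    rows = []
    duration = cfg.tonic_pre_s + cfg.tonic_post_s

    def _one(cohort, cell, seed, amp):
        trace, truth = simulate_tonic_block_experiment(
            pre_duration=cfg.tonic_pre_s, post_duration=cfg.tonic_post_s,
            tonic_amplitude_pa=amp, mipsc_rate=cfg.mipsc_rate,
            noise_sd=cfg.vc_noise_sd, sampling_rate=cfg.vc_sampling_rate,
            seed=seed,
        )
        res = tonic_current_amplitude(trace, (0.0, cfg.tonic_pre_s),
                                      (cfg.tonic_pre_s, duration))
        return {"cohort": cohort, "cell": cell, "seed": seed,
                "qc_accepted": True, "qc_reason": "ok",
                "true_tonic_pa": truth.tonic_step_pa,
                "tonic_amplitude_pa": res.tonic_amplitude,
                "i_hold_baseline_pa": res.i_hold_baseline,
                "i_hold_drug_pa": res.i_hold_drug}

    for i in range(cfg.n_cells):
        rows.append(_one("treated", i, seeds[i], cfg.tonic_amplitude_pa))
    for i in range(cfg.n_control):
        rows.append(_one("control", i, seeds[cfg.n_cells + i], cfg.control_tonic_pa))
    cells = pd.DataFrame(rows)
    treated = cells[cells.cohort == "treated"]["tonic_amplitude_pa"].to_numpy()
    control = cells[cells.cohort == "control"]["tonic_amplitude_pa"].to_numpy()
    results = steel_test(control, [treated], method="mc",
                         n_draws=cfg.stats_n_draws, seed=cfg.seed)
    return cells, results


def run_scenario(config: ScenarioConfig, out_dir=None) -> Report:
    """Run a full scenario; optionally write ``cells.csv``/``stats.csv``/
    ``report.json`` to ``out_dir``.  Deterministic given the config seed."""
    if config.scenario.startswith("repetitive"):
        cells, results = _run_repetitive(config)
    elif config.scenario.startswith("single_shot"):
        cells, results = _run_single_shot(config)
    else:
        cells, results = _run_tonic(config)
    report = Report(
        cells=cells,
        stats=_stats_frame(results),
        config=config.to_dict(),
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__},
    )
    if out_dir is not None:
        report.save(out_dir)
    return report
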