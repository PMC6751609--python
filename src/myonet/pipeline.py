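"""End-to-end pipeline driver.

simulate -> preprocess -> PSD -> IMCoh -> MVAR/PDC -> frequency components ->
graph metrics -> synergies -> gait & posture -> group statistics, with every
stage parameter and derived seed recorded in a JSON manifest so a re-run from
the same manifest reproduces all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn_mod
from . import gait_posture as gp
from . import preprocess, stats, synergy, synthetic
from .components import select_K
from .network import metrics_per_component

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("myonet")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    outdir: str = "myonet_out"
    groups: dict[str, int] = field(
        default_factory=lambda: {"HC": 10, "DM1": 7})
    base_seed: int = 0
    n_trials: int = 2                  # walking trials per subject
    n_cycles: int | None = None        # override preset cycle count
    band_hz: tuple[float, float] = (0.5, 70.0)
    fs_out: float = 200.0
    window_s: float = 1.0
    overlap: float = 0.75
    max_order: int = 12
    vaf_threshold_pct: float = 90.0
    k_max: int = 8
    K_max_components: int = 8
    n_restarts: int = 10
    n_restarts_components: int = 5
    n_phase_points: int = 200
    cop_duration_s: float = 120.0
    cop_rate_hz: float = 50.0
    # COP sway SDs (mm): [group][condition] -> (AP, ML)
    cop_sigma_mm: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "HC": {"eyes_open": (3.0, 2.0), "eyes_closed": (3.3, 2.2)},
            "DM1": {"eyes_open": (4.5, 3.2), "eyes_closed": (4.8, 3.4)},
        })


@dataclass
class PipelineResult:
    manifest: dict
    subject_table: pd.DataFrame
    group_components: dict[str, dict[str, object]]
    group_metrics: dict[str, dict[str, list]]
    stats_report: dict
    outdir: Path


def _subject_seed(base: int, group: str, idx: int, what: int) -> int:
    # deterministic, collision-free derivation, kept below 2**31
    g = {"HC": 1, "DM1": 2}.get(group, 3)
    return (base * 1_000_003 + g * 10_007 + idx * 101 + what) % (2 ** 31 - 1)


def _analyze_subject(cfg: PipelineConfig, group: str, idx: int,
                     outdir: Path) -> dict:
    sid = f"{group}{idx:02d}"
    gen = synthetic.preset(group)
    if cfg.n_cycles is not None:
        gen = dataclasses.replace(gen, n_cycles=cfg.n_cycles)
    trials = []
    env_trials = []
    for tr in range(cfg.n_trials):
        g = dataclasses.replace(gen, subject_id=sid,
                                seed=_subject_seed(cfg.base_seed, group, idx, tr))
        rec = synthetic.generate_emg(g)
        synthetic.write_emg_recording(rec, outdir / "emg" / f"{sid}_t{tr}")
        trials.append(rec)
        env_trials.append(preprocess.make_envelopes(
            rec, band_hz=cfg.band_hz, fs_out=cfg.fs_out))

    env = env_trials[0]
    spec = conn_mod.normalized_psd(env, cfg.window_s, cfg.overlap)
    coh = conn_mod.imcoh(env_trials, cfg.window_s, cfg.overlap)
    mvar = conn_mod.fit_mvar(env, max_order=cfg.max_order)
    pdc_spec = conn_mod.pdc(mvar) if mvar.stable else None
    validation = conn_mod.validate_mvar(mvar, coh)

    epochs = preprocess.epoch_by_cycles(env, trials[0], cfg.n_phase_points)
    model = synergy.select_n_synergies(
        epochs.concatenated(), threshold_pct=cfg.vaf_threshold_pct,
        k_max=cfg.k_max, seed=_subject_seed(cfg.base_seed, group, idx, 50),
        n_restarts=cfg.n_restarts, channel_labels=env.channel_labels)
    per_cycle = [
        synergy.nmf_lee_seung(
            synergy.scale_rows_unit_variance(ep), model.k,
            seed=_subject_seed(cfg.base_seed, group, idx, 60 + c),
            n_restarts=max(2, cfg.n_restarts // 4))
        for c, ep in enumerate(epochs.normalized_epochs)
    ]
    variability = synergy.cycle_variability(per_cycle)

    gait = gp.gait_parameters(trials[0].heel_strikes, trials[0].toe_offs)
    sig = cfg.cop_sigma_mm[group]
    eo = synthetic.generate_cop(*sig["eyes_open"],
                                duration_s=cfg.cop_duration_s,
                                rate_hz=cfg.cop_rate_hz,
                                seed=_subject_seed(cfg.base_seed, group, idx, 70))
    ec = synthetic.generate_cop(*sig["eyes_closed"],
                                duration_s=cfg.cop_duration_s,
                                rate_hz=cfg.cop_rate_hz,
                                seed=_subject_seed(cfg.base_seed, group, idx, 71),
                                condition="eyes_closed")
    cop = gp.cop_metrics(eo, ec)

    return {
        "subject_id": sid, "group": group,
        "psd": spec, "imcoh": coh, "pdc": pdc_spec, "mvar_order": mvar.order_p,
        "mvar_valid_pairs": int(len(validation.pair_labels)
                                - len(validation.flagged)),
        "n_synergies": model.k, "synergy_vaf": model.vaf_pct,
        "w_similarity": variability.w_similarity_mean,
        "c_dispersion": variability.c_dispersion_cv,
        "gcd_s": gait.gcd_s, "cadence_hz": gait.cadence_hz, "ssr": gait.ssr,
        "cop_path_mm": cop.path_length_mm,
        "ellipse_mm2": cop.ellipse_area_mm2,
        "romberg": cop.romberg_quotient,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis for every synthetic subject and both groups."""
    t0 = time.time()
    outdir = Path(config.outdir)
    for sub in ("emg", "connectivity", "components", "stats"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    rows, per_subject = [], []
    for group, n_subj in config.groups.items():
        if group not in ("HC", "DM1"):
            raise ValueError(f"unknown group preset {group!r}")
        for idx in range(n_subj):
            t_s = time.time()
            try:
                res = _analyze_subject(config, group, idx, outdir)
            except Exception as exc:
                raise RuntimeError(
                    f"stage failure for subject {group}{idx:02d}: {exc}"
                ) from exc
            per_subject.append(res)
            rows.append({k: v for k, v in res.items()
                         if k not in ("psd", "imcoh", "pdc")})
            log.info("subject %s done in %.1f s", res["subject_id"],
                     time.time() - t_s)

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "subjects.csv", index=False)

    # group-mean connectivity -> frequency components -> graph metrics
    group_components: dict[str, dict[str, object]] = {}
    group_metrics: dict[str, dict[str, list]] = {}
    for group in config.groups:
        subs = [r for r in per_subject if r["group"] == group]
        group_components[group] = {}
        group_metrics[group] = {}
        for est in ("imcoh", "pdc"):
            specs = [r[est] for r in subs if r[est] is not None]
            if not specs:
                continue
            mean_vals = np.mean([s.values for s in specs], axis=0)
            ref = specs[0]
            mean_conn = conn_mod.ConnectivitySpectra(
                directed=ref.directed, pair_labels=ref.pair_labels,
                values=mean_vals, estimator=ref.estimator,
                bin_centers_hz=ref.bin_centers_hz,
                channel_labels=ref.channel_labels)
            fc = select_K(mean_conn, config.vaf_threshold_pct,
                          config.K_max_components,
                          n_restarts=config.n_restarts_components,
                          seed=config.base_seed + 17)
            group_components[group][est] = fc
            group_metrics[group][est] = metrics_per_component(fc)
            _dump_components(outdir / "components" / f"{group}_{est}.json", fc)

    stats_report = _group_statistics(table, per_subject)
    (outdir / "stats" / "report.json").write_text(
        json.dumps(stats_report, indent=1, default=float))

    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "seeds": {r["subject_id"]: _subject_seed(
            config.base_seed, r["group"],
            int(r["subject_id"][-2:]), 0) for r in per_subject},
        "runtime_s": time.time() - t0,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return PipelineResult(manifest=manifest, subject_table=table,
                          group_components=group_components,
                          group_metrics=group_metrics,
                          stats_report=stats_report, outdir=outdir)


def _dump_components(path: Path, fc) -> None:
    path.write_text(json.dumps({
        "K": fc.n_components_K,
        "vaf_curve": fc.vaf_curve,
        "centroids_hz": fc.centroids_hz.tolist(),
        "spectral_signatures": fc.spectral_signatures.tolist(),
        "edge_weights": fc.edge_weights.tolist(),
        "pair_labels": [list(p) for p in fc.pair_labels],
    }, indent=1))


def _group_statistics(table: pd.DataFrame, per_subject: list[dict]) -> dict:
    """One-way group ANOVAs on the scalar metrics + PSD group x bin ANOVA."""
    report: dict[str, dict] = {"anova": {}}
    if table["group"].nunique() < 2:
        return report
    for metric in ("gcd_s", "cadence_hz", "ssr", "cop_path_mm", "ellipse_mm2",
                   "romberg", "n_synergies", "w_similarity", "c_dispersion"):
        try:
            res = stats.anova(table, metric, ["group"],
                              posthoc_factor="group")[0]
        except Exception as exc:  # e.g. a single-subject group
            report["anova"][metric] = {"error": str(exc)}
            continue
        report["anova"][metric] = {
            "F": res.F, "df": res.df, "p": res.p, "eta_sq": res.eta_sq,
            "posthoc": res.posthoc}
    # PSD: group x frequency-bin factorial on channel-mean normalized power
    rows = []
    for r in per_subject:
        mean_psd = r["psd"].psd.mean(axis=0)
        for f, v in zip(r["psd"].bin_centers_hz, mean_psd):
            rows.append({"subject": r["subject_id"], "group": r["group"],
                         "bin_hz": f, "power": v})
    psd_df = pd.DataFrame(rows)
    for res in stats.anova(psd_df, "power", ["group", "bin_hz"]):
        report["anova"][f"psd[{res.effect_label}]"] = {
            "F": res.F, "df": res.df, "p": res.p, "eta_sq": res.eta_sq}
    return report
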