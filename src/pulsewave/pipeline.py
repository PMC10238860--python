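"""End-to-end analysis pipeline and command-line interface.

``analyze_recording`` runs load -> filter -> beat detection -> ensemble
averaging -> pulse wave analysis -> wave separation -> wave power on each
ensemble group, twice when flow is available (measured flow and
pressure-only synthetic flow), and assembles a session report with
method-agreement statistics (Bland--Altman mean bias and 95% limits of
agreement, Spearman's rho) between the two flow sources.

The CLI exposes three subcommands::

    pulsewave simulate --preset baseline --beats 40 --seed 7 --out s.csv
    pulsewave analyze s.csv --out report.csv
    pulsewave compare a.csv b.csv c.csv --out agreement.csv
"""

from __future__ import annotations

import argparse
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess, pwa, synthetic_data, synthetic_flow, waveform_io, wpa, wsa
from .config import AnalysisConfig
from .errors import (
    ClassificationError,
    DegenerateBeatError,
    FitError,
    PulsewaveError,
    SessionError,
    SynthesisError,
    WindowError,
)
from .waveform_io import Recording

__all__ = ["SessionReport", "analyze_recording", "bland_altman",
           "spearman_rho", "cli_main", "main"]

logger = logging.getLogger(__name__)

#: Indices compared between measured- and synthetic-flow computations.
PAIRED_INDICES = ("pf_amp", "pb_amp", "rm", "qzc_int", "wasted_effort",
                  "wasted_ratio", "fcw_few_ratio")


@dataclass
class SessionReport:
    """Per-ensemble-group index rows plus session-level agreement."""

    rows: pd.DataFrame
    agreement: pd.DataFrame | None
    n_groups: int
    n_excluded_groups: int
    n_excluded_beats: int
    provenance: dict = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        """Session mean of every numeric index, per flow source."""
        num = self.rows.select_dtypes(include=[np.number]).columns
        return self.rows.groupby("flow_source", sort=True)[list(num)].mean()


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean bias and 95% limits of agreement of paired measurements.

    Differences are ``x - y``; the limits are ``bias +/- 1.96 * SD`` with the
    sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise SessionError("paired samples must have equal length")
    if x.size < 2:
        raise SessionError("Bland-Altman needs at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def spearman_rho(x, y) -> float | None:
    """Spearman's rank correlation (average ranks for ties).

    Returns ``None`` when undefined (n < 3 or zero rank variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise SessionError("paired samples must have equal length")
    if x.size < 3:
        return None
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def _wpa_block(p_bar, q_arr, dn_idx, fs_eff, config, calibrated: bool) -> dict:
    dpi, dP, dQ, fs_grid = wpa.wave_power(p_bar, q_arr, fs_eff, config)
    scale = fs_grid / fs_eff
    ppeak = int(round(np.argmax(p_bar) * scale))
    dn = int(round(dn_idx * scale))
    res = wpa.classify_waves(dpi, dP, dQ, ppeak, dn, fs_grid, config)
    out = {"fcw_few_ratio": res.fcw_few_ratio,
           "bcw_present": res.bcw is not None}
    if calibrated:
        out["fcw_height_uw"] = res.fcw.height
        out["few_height_uw"] = res.few.height if res.few else np.nan
        out["bcw_height_uw"] = res.bcw.height if res.bcw else np.nan
        out["fcw_time_ms"] = res.fcw.time_ms
        out["bcw_time_ms"] = res.bcw.time_ms if res.bcw else np.nan
    return out


def analyze_recording(
    rec: Recording, config: AnalysisConfig | None = None
) -> SessionReport:
    """Run the full analysis chain on one recording.

    Requires at least one complete ensemble group (``group_size`` beats,
    default 8). Deterministic for a fixed (recording, config) pair. When
    flow is absent the pressure-only path runs (pulse wave analysis plus the
    synthetic-flow wave indices) and no agreement block is produced.
    """
    config = config or AnalysisConfig()
    fs = rec.fs_hz
    # Two smoothing tracks: the landmark chain runs on the heavily low-passed
    # pressure, while the pressure--flow wave analyses keep the notch and
    # shoulder by using only the polynomial measurement smoothing.
    p_f = preprocess.filter_pressure(rec.p, fs, config)
    p_w = preprocess.smooth_signal(rec.p, config)
    q_w = preprocess.smooth_signal(rec.q, config) if rec.q is not None else None
    beats = preprocess.detect_beats(p_f, fs, config)
    if len(beats) < config.group_size:
        raise SessionError(
            f"{len(beats)} beats detected; a complete ensemble group requires "
            f"{config.group_size} beats"
        )
    ensembles = preprocess.ensemble_average(beats, p_f, config, q=q_w, fs_hz=fs,
                                            p_dim=p_w)

    rows: list[dict] = []
    n_excluded_groups = 0
    n_excluded_beats = 0
    for gi, ens in enumerate(ensembles):
        lm = pwa.locate_landmarks(ens)
        if not lm.valid:
            logger.warning("group %d excluded: %s", gi, lm.reason)
            n_excluded_groups += 1
            n_excluded_beats += len(ens.member_beats)
            continue
        per_beat = pwa.indices_for_ensemble(ens, lm, p_f, fs)
        n_excluded_beats += len(ens.member_beats) - len(per_beat)
        try:
            agg = pwa.aggregate_session(per_beat)
        except PulsewaveError as exc:
            logger.warning("group %d excluded at PWA aggregation: %s", gi, exc)
            n_excluded_groups += 1
            continue
        pwa_fields = {k[:-5]: v for k, v in agg.items() if k.endswith("_mean")}

        # Wave analyses run on the foot-aligned signal-averaged beat, which
        # lives on the recording's own time grid; landmark indices found on
        # the normalized waveform are mapped onto that grid.
        p_bar = ens.p_mean
        lm_wave = pwa.PwaLandmarks(
            p1_idx=ens.wave_index(lm.p1_idx),
            p2_idx=ens.wave_index(lm.p2_idx),
            dn_idx=ens.wave_index(lm.dn_idx),
            augmentation_sign=lm.augmentation_sign, valid=True)
        base = {"group": gi, "augmentation": lm.augmentation_sign,
                "n_beats": agg["n_beats"], **pwa_fields}

        if ens.q_mean is not None:
            try:
                fit = wsa.estimate_zc(p_bar, ens.q_mean, fs, config)
                sep = wsa.separate_waves(p_bar, ens.q_mean, fit.zc, fit)
                qzc_int, wasted, ratio = wsa.wasted_effort_indices(
                    p_bar, ens.q_mean, fit.zc, lm_wave.dn_idx, fs)
                sv = float(np.trapezoid(np.maximum(ens.q_mean, 0.0),
                                        dx=1.0 / fs))
                row = dict(base, flow_source="measured",
                           zc_mmhg_s_per_ml=fit.zc,
                           zc_mmhg_min_per_l=wsa.report_zc_units(fit.zc),
                           zc_fit_r2=fit.r_squared,
                           pf_amp=sep.pf_amp, pb_amp=sep.pb_amp, rm=sep.rm,
                           qzc_int=qzc_int, wasted_effort=wasted,
                           wasted_ratio=ratio, sv_ml=sv)
                row.update(_wpa_block(p_bar, ens.q_mean, lm_wave.dn_idx, fs,
                                      config, calibrated=True))
                rows.append(row)
            except (WindowError, FitError, DegenerateBeatError,
                    ClassificationError) as exc:
                logger.warning("group %d measured-flow block failed: %s", gi, exc)

        try:
            sf = synthetic_flow.synthesize_flow(p_bar, lm_wave, fs)
            syn = synthetic_flow.wsa_wpa_from_synthetic(
                p_bar, sf.qs, lm_wave, fs, config)
            rows.append(dict(base, flow_source="synthetic",
                             pf_amp=syn.pf_amp, pb_amp=syn.pb_amp, rm=syn.rm,
                             qzc_int=syn.qzc_int,
                             wasted_effort=syn.wasted_effort,
                             wasted_ratio=syn.wasted_ratio,
                             fcw_few_ratio=syn.fcw_few_ratio))
        except (SynthesisError, WindowError, FitError, DegenerateBeatError,
                ClassificationError) as exc:
            logger.warning("group %d synthetic-flow block failed: %s", gi, exc)

    if not rows:
        raise SessionError("no ensemble group produced a valid analysis")
    df = pd.DataFrame(rows)

    agreement = None
    if "flow_source" in df.columns and {"measured", "synthetic"} <= set(
            df["flow_source"]):
        meas = df[df.flow_source == "measured"].set_index("group")
        syn = df[df.flow_source == "synthetic"].set_index("group")
        common = meas.index.intersection(syn.index)
        if len(common) >= 2:
            recs = []
            for name in PAIRED_INDICES:
                x = meas.loc[common, name].to_numpy(dtype=float)
                y = syn.loc[common, name].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 2:
                    continue
                bias, lo, hi = bland_altman(x[ok], y[ok])
                recs.append({"index": name, "bias": bias, "loa_low": lo,
                             "loa_high": hi, "n": int(ok.sum()),
                             "spearman_rho": spearman_rho(x[ok], y[ok])})
            if recs:
                agreement = pd.DataFrame(recs)

    return SessionReport(
        rows=df,
        agreement=agreement,
        n_groups=len(ensembles),
        n_excluded_groups=n_excluded_groups,
        n_excluded_beats=n_excluded_beats,
        provenance={
            "config_digest": config.digest(),
            "n_samples": rec.n_samples,
            "fs_hz": fs,
            "source": rec.meta.get("source", "<memory>"),
        },
    )


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="pulsewave",
        description="Pulse wave / wave separation / wave power analysis of "
                    "aortic pressure-flow waveforms.",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    sim = sub.add_parser("simulate", help="write a simulated paired recording")
    sim.add_argument("--preset", choices=synthetic_data.PRESET_STAGES,
                     default="baseline")
    sim.add_argument("--beats", type=int, default=40)
    sim.add_argument("--seed", type=int, default=0)
    sim.add_argument("--out", required=True)
    sim.add_argument("--noise-sd-mmhg", type=float, default=None)
    sim.add_argument("--gamma", type=float, default=None)
    sim.add_argument("--no-flow", action="store_true",
                     help="omit the flow column (pressure-only file)")

    ana = sub.add_parser("analyze", help="analyze a waveform CSV")
    ana.add_argument("input")
    ana.add_argument("--out", required=True)
    ana.add_argument("--config", default=None)
    ana.add_argument("--flow-unit", default=None,
                     help="unit of a non-canonical flow column")
    ana.add_argument("--plot", default=None, help="optional PNG path")

    cmp_ = sub.add_parser("compare",
                          help="measured-vs-synthetic agreement across sessions")
    cmp_.add_argument("inputs", nargs="+")
    cmp_.add_argument("--out", required=True)
    cmp_.add_argument("--config", default=None)
    return parser


def _cmd_simulate(args) -> int:
    overrides = {"seed": args.seed}
    if args.noise_sd_mmhg is not None:
        overrides["noise_sd_mmhg"] = args.noise_sd_mmhg
    if args.gamma is not None:
        overrides["gamma"] = args.gamma
    params = synthetic_data.hf_preset(args.preset, **overrides)
    rec = synthetic_data.simulate_recording(params, args.beats)
    if args.no_flow:
        rec.q = None
    out = Path(args.out)
    waveform_io.write_recording(rec, out)
    truth = dict(rec.meta["truth"])
    truth["onsets"] = rec.meta["onsets"]
    waveform_io.write_truth_sidecar(truth, out.with_suffix(".truth.txt"))
    logger.info("simulate: wrote %s (%d beats, preset %s)",
                out, args.beats, args.preset)
    return 0


def _load_config(path: str | None) -> AnalysisConfig:
    return AnalysisConfig.from_file(path) if path else AnalysisConfig()


def _cmd_analyze(args) -> int:
    config = _load_config(args.config)
    io_cfg = {"flow_unit": args.flow_unit} if args.flow_unit else None
    rec = waveform_io.read_recording(args.input, io_cfg)
    report = analyze_recording(rec, config)
    waveform_io.write_report(report.rows, args.out)
    if report.agreement is not None:
        agree_path = Path(args.out).with_suffix(".agreement.csv")
        report.agreement.to_csv(agree_path, index=False, float_format="%.10g")
        logger.info("analyze: agreement block -> %s", agree_path)
    if args.plot:
        _plot_session(rec, report, args.plot, config)
    logger.info("analyze: %d groups (%d excluded), report -> %s",
                report.n_groups, report.n_excluded_groups, args.out)
    return 0


def _cmd_compare(args) -> int:
    config = _load_config(args.config)
    pooled: list[pd.DataFrame] = []
    summaries: list[pd.DataFrame] = []
    for path in args.inputs:
        rec = waveform_io.read_recording(path)
        rep = analyze_recording(rec, config)
        rows = rep.rows.copy()
        rows.insert(0, "session", Path(path).stem)
        pooled.append(rows)
        summ = rep.summary.reset_index()
        summ.insert(0, "session", Path(path).stem)
        summaries.append(summ)
    allrows = pd.concat(pooled, ignore_index=True)

    recs = []
    if "flow_source" in allrows.columns:
        meas = allrows[allrows.flow_source == "measured"]
        syn = allrows[allrows.flow_source == "synthetic"]
        key = ["session", "group"]
        merged = meas.merge(syn, on=key, suffixes=("_m", "_s"))
        for name in PAIRED_INDICES:
            xm, xs = f"{name}_m", f"{name}_s"
            if xm not in merged or xs not in merged:
                continue
            x = merged[xm].to_numpy(dtype=float)
            y = merged[xs].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 2:
                continue
            bias, lo, hi = bland_altman(x[ok], y[ok])
            recs.append({"index": name, "bias": bias, "loa_low": lo,
                         "loa_high": hi, "n": int(ok.sum()),
                         "spearman_rho": spearman_rho(x[ok], y[ok])})
    out = Path(args.out)
    pd.DataFrame(recs).to_csv(out, index=False, float_format="%.10g")
    pd.concat(summaries, ignore_index=True).to_csv(
        out.with_suffix(".sessions.csv"), index=False, float_format="%.10g")
    logger.info("compare: %d sessions pooled -> %s", len(args.inputs), out)
    return 0


def _plot_session(rec: Recording, report: SessionReport, path: str,
                  config: AnalysisConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    axes[0].plot(rec.t, rec.p, lw=0.8, color="k")
    axes[0].set_ylabel("pressure (mmHg)")
    if rec.q is not None:
        axes[1].plot(rec.t, rec.q, lw=0.8, color="gray")
    axes[1].set_ylabel("flow (mL/s)")
    axes[1].set_xlabel("time (s)")
    fig.suptitle(f"{report.provenance.get('source', '')} "
                 f"({report.n_groups} ensemble groups)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cli_main(argv: list[str] | None = None) -> int:
    """Entry point; returns a process exit status (0 ok, 1 error, 2 usage)."""
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    try:
        if args.command == "simulate":
            return _cmd_simulate(args)
        if args.command == "analyze":
            return _cmd_analyze(args)
        if args.command == "compare":
            return _cmd_compare(args)
        parser.error(f"unknown command {args.command!r}")
    except PulsewaveError as exc:
        logger.error("%s: %s", type(exc).__name__, exc)
        return 1
    except OSError as exc:
        logger.error("I/O failure: %s", exc)
        return 1
    return 2


def main() -> None:  # console-script shim
    sys.exit(cli_main())
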