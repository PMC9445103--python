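"""End-to-end runner: configuration, seeding, and the full analysis graph.

``run_pipeline`` reproduces the study's analysis order on synthetic data —
behavior, 3-D time-frequency cluster test, time-resolved decoding,
retro-cue alpha lateralization, and interval-of-interest Bayesian t tests —
and emits a machine-readable results dictionary plus a human-readable
summary.  Every stochastic stage derives its seed deterministically from
the global seed and the stage name, so a rerun with the same configuration
is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import decoding as dec
from . import inference as inf
from . import lateralization as lat
from . import montage
from . import simulate as sim
from . import tfr as tfrm
from ._utils import bin_downsample, derive_seed, window_mask

logger = logging.getLogger("taskprio")

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """Raised by ``validate_config`` with the full list of violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults are the study's constants."""

    seed: int = 0
    n_subjects: int = 28
    n_blocks: int = 10
    trials_per_block: int = 60
    effects: str | sim.EffectSpec = "default"  # "default", "null" or explicit
    freqs_hz: list | None = None        # None -> 19 wavelets, 2-20 Hz
    stats_sfreq: float = 20.0           # time resolution of the 3-D cluster test
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    decode_features: list = field(default_factory=lambda: ["broadband_erp"])
    decode_n_groups: int = 15
    decode_n_iterations: int = 10
    decode_time_range_ms: tuple = (0.0, 11800.0)
    lateralization_band_hz: tuple = (8.0, 15.0)
    prior_scale: float = 0.707
    decode_fallback_window_ms: tuple = (5600.0, 8000.0)
    lat_fallback_window_ms: tuple = (9600.0, 10800.0)
    allow_band_override: bool = False
    version: int = CONFIG_VERSION

    def effect_spec(self, seed: int) -> sim.EffectSpec:
        if self.effects == "default":
            return sim.default_effect_spec(seed)
        if self.effects == "null":
            return sim.null_effect_spec(seed)
        if isinstance(self.effects, sim.EffectSpec):
            return dataclasses.replace(self.effects, seed=seed)
        raise ConfigError([f"unknown effects setting {self.effects!r}"])


def validate_config(raw: dict | RunConfig | None) -> RunConfig:
    """Fill defaults and check cross-field consistency; collects *all*
    violations into one :class:`ConfigError`."""
    if raw is None:
        raw = {}
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError([f"unknown config keys: {unknown}"])
        cfg = RunConfig(**raw)
    errors = []
    if cfg.n_subjects < 2:
        errors.append("n_subjects must be >= 2 for paired statistics")
    if cfg.trials_per_block % 4:
        errors.append("trials_per_block must be divisible by 4")
    freqs = np.asarray(cfg.freqs_hz if cfg.freqs_hz is not None
                       else tfrm.DEFAULT_FREQS_HZ, dtype=float)
    if not cfg.allow_band_override and (freqs.min() < 2.0 or freqs.max() > 20.0):
        errors.append("wavelet frequencies outside 2-20 Hz require allow_band_override")
    lo, hi = cfg.lateralization_band_hz
    if hi < lo:
        errors.append("lateralization band end below start")
    if not ((freqs >= lo) & (freqs <= hi)).any():
        errors.append("no wavelet frequencies inside the lateralization band")
    for name in ("decode_time_range_ms", "decode_fallback_window_ms",
                 "lat_fallback_window_ms"):
        a, b = getattr(cfg, name)
        if b < a:
            errors.append(f"{name} end before start")
    for kind in cfg.decode_features:
        if kind not in ("broadband_erp", "alpha_power"):
            errors.append(f"unknown decode feature kind {kind!r}")
    if cfg.version != CONFIG_VERSION:
        errors.append(f"config version {cfg.version} != supported {CONFIG_VERSION}")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# per-subject analysis
# --------------------------------------------------------------------------

def _sig_time_window(result: cl.ClusterTestResult, times_ms: np.ndarray):
    """Time points inside any significant cluster, or None."""
    sig = result.mask if result.mask.ndim == 1 else result.mask.any((0, 1))
    if not sig.any():
        return None
    return sig


def _subject_condition_stats(epochs, cfg: RunConfig, subject_seed: int):
    """One subject's stage outputs, streaming the TFR one frequency at a
    time so paper-scale trial counts stay within memory."""
    meta = epochs.metadata
    freqs = np.asarray(cfg.freqs_hz if cfg.freqs_hz is not None
                       else tfrm.DEFAULT_FREQS_HZ, dtype=float)
    cond_masks = {c: (meta["important_task"] == c).to_numpy() for c in sim.TASKS}

    lat_band = cfg.lateralization_band_hz
    lat_freqs = freqs[(freqs >= lat_band[0]) & (freqs <= lat_band[1])]
    balanced = {
        c: np.flatnonzero(cond_masks[c])[
            lat.draw_balanced_trials(meta[cond_masks[c]],
                                     derive_seed(subject_seed, f"balance-{c}"))]
        for c in sim.TASKS
    }

    db_means = {c: [] for c in sim.TASKS}
    lat_curves = {c: [] for c in sim.TASKS}
    alpha_needed = "alpha_power" in cfg.decode_features
    alpha_cfg = dec.DecodingConfig(
        feature_kind="alpha_power", n_groups=cfg.decode_n_groups,
        n_iterations=cfg.decode_n_iterations, time_range_ms=cfg.decode_time_range_ms)
    alpha_feats = []

    for f in freqs:
        bank = tfrm.build_wavelets(epochs.sfreq, np.array([f]))
        tfr_f = tfrm.decompose(epochs, bank)
        db_f = tfrm.db_baseline(tfr_f)
        for c, mask in cond_masks.items():
            mean_db = db_f.power[mask].mean(0)  # (ch, 1, t)
            db_means[c].append(mean_db[:, 0])
        if f in lat_freqs:
            for c in sim.TASKS:
                r = lat.lateralization_index(tfr_f, meta, trials=balanced[c])
                lat_curves[c].append(r.index[:, 0].mean(0))  # pair-avg (t,)
        if alpha_needed and f in alpha_cfg.alpha_freqs_hz:
            x, feat_times = dec.prepare_features(
                tfr_f, dataclasses.replace(alpha_cfg, alpha_freqs_hz=(f,)))
            alpha_feats.append(x)
        lat_times = tfr_f.times_ms

    out = {}
    factor = int(round(epochs.sfreq / cfg.stats_sfreq))
    out["db_means"] = {
        c: bin_downsample(np.stack(v, axis=1), factor, axis=-1)
        for c, v in db_means.items()}  # (ch, freq, t20)
    out["db_times_ms"] = bin_downsample(lat_times, factor)
    out["lat_curves"] = {c: np.stack(v).mean(0) for c, v in lat_curves.items()}
    out["lat_times_ms"] = lat_times

    out["decoding"] = {}
    for kind in cfg.decode_features:
        curves = {}
        for c, mask in cond_masks.items():
            if kind == "broadband_erp":
                sub = dataclasses.replace(epochs, data=epochs.data[mask],
                                          metadata=meta[mask].reset_index(drop=True))
                model = dec.GroupAverageDecoder(
                    sub, meta.loc[mask, "classification_type"].to_numpy(),
                    dec.DecodingConfig(
                        feature_kind=kind, n_groups=cfg.decode_n_groups,
                        n_iterations=cfg.decode_n_iterations,
                        time_range_ms=cfg.decode_time_range_ms))
                res = model.fit(derive_seed(subject_seed, f"decode-{kind}-{c}"))
                times = model.times_ms
            else:
                feats = np.concatenate(alpha_feats, axis=1)[mask]
                res = dec.decode_timecourse(
                    feats, meta.loc[mask, "classification_type"].to_numpy(),
                    alpha_cfg, derive_seed(subject_seed, f"decode-{kind}-{c}"))
                times = feat_times
            curves[c] = res.accuracy_smoothed
        out["decoding"][kind] = {"curves": curves, "times_ms": times}
    return out


# --------------------------------------------------------------------------
# group-level pipeline
# --------------------------------------------------------------------------

def _interval_stats(curves_by_cond, times, sig_mask, fallback_window, reference, prior):
    """Interval-averaged one-sample and paired tests, Bayes factors included."""
    if sig_mask is not None:
        window_desc = [float(times[sig_mask].min()), float(times[sig_mask].max())]
        def avg(c):
            return c[:, sig_mask].mean(1)
        source = "significant_cluster_timepoints"
    else:
        m = window_mask(times, fallback_window)
        window_desc = list(fallback_window)
        def avg(c):
            return c[:, m].mean(1)
        source = "fallback_window"
    a, b = (curves_by_cond[c] for c in sim.TASKS)
    return {
        "window_ms": window_desc,
        "window_source": source,
        "vs_reference": {c: inf.t_test(avg(curves_by_cond[c]), reference,
                                       prior).to_dict() for c in sim.TASKS},
        "condition_contrast": inf.t_test(avg(a), avg(b), prior).to_dict(),
    }


def run_pipeline(config: dict | RunConfig | None, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic-data analysis graph and return the results
    dictionary (also written as JSON + summary when ``out_dir`` is given)."""
    cfg = validate_config(config)
    logger.info("pipeline start: seed=%d, %d subjects", cfg.seed, cfg.n_subjects)

    behavior_rows = []
    subj_stats = []
    for s in range(cfg.n_subjects):
        s_seed = derive_seed(cfg.seed, f"subject-{s}")
        spec = cfg.effect_spec(derive_seed(s_seed, "eeg"))
        epochs = sim.simulate_subject(
            s_seed, cfg.n_blocks, cfg.trials_per_block, spec=spec)
        meta = epochs.metadata
        for c in sim.TASKS:
            m = meta[meta["important_task"] == c]
            behavior_rows.append({
                "subject": s, "condition": c,
                "rt_nct_ms": m["rt_nct_ms"].mean(),
                "error_rate_nct": 1.0 - m["correct_nct"].mean(),
                "rt_wmt_ms": m["rt_wmt_ms"].mean(),
                "deviation_deg": m["deviation_deg"].mean(),
                "fp_total": m["fp_total"].mean(),
            })
        subj_stats.append(_subject_condition_stats(epochs, cfg, s_seed))
        logger.info("subject %d/%d done", s + 1, cfg.n_subjects)

    results: dict = {"config": _config_dict(cfg)}

    behavior = pd.DataFrame(behavior_rows)
    results["behavior"] = {}
    for measure in ("rt_nct_ms", "rt_wmt_ms", "deviation_deg", "error_rate_nct"):
        piv = behavior.pivot(index="subject", columns="condition", values=measure)
        results["behavior"][measure] = {
            "mean": {c: float(piv[c].mean()) for c in sim.TASKS},
            "sd": {c: float(piv[c].std(ddof=1)) for c in sim.TASKS},
            "paired_test": inf.t_test(piv["NCT"].to_numpy(), piv["WMT"].to_numpy(),
                                      cfg.prior_scale).to_dict(),
        }

    # 3-D cluster test on dB power, NCT important vs WMT important
    graph = cl.build_adjacency(montage.load_montage())
    cond = {c: np.stack([st["db_means"][c] for st in subj_stats]) for c in sim.TASKS}
    test3d = cl.paired_cluster_test_3d(
        cond["NCT"], cond["WMT"], graph,
        n_permutations=cfg.n_permutations, cluster_alpha=cfg.cluster_alpha,
        alpha=cfg.alpha, seed=derive_seed(cfg.seed, "cluster3d"))
    times20 = subj_stats[0]["db_times_ms"]
    freqs = np.asarray(cfg.freqs_hz if cfg.freqs_hz is not None
                       else tfrm.DEFAULT_FREQS_HZ, dtype=float)
    results["tfr_cluster"] = _cluster_dict(test3d, axes={
        "freqs_hz": freqs.tolist(), "times_ms": times20.tolist()})

    # decoding: 1-D cluster tests vs chance + interval Bayes stats
    results["decoding"] = {}
    for kind, block0 in subj_stats[0]["decoding"].items():
        times = np.asarray(block0["times_ms"], float)
        curves = {c: np.stack([st["decoding"][kind]["curves"][c] for st in subj_stats])
                  for c in sim.TASKS}
        vs_chance = {
            c: cl.cluster_test_1d(
                curves[c], 0.5, n_permutations=cfg.n_permutations,
                cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
                seed=derive_seed(cfg.seed, f"decode1d-{kind}-{c}"))
            for c in sim.TASKS}
        paired = cl.cluster_test_1d(
            curves["NCT"], paired_partner=curves["WMT"],
            n_permutations=cfg.n_permutations, cluster_alpha=cfg.cluster_alpha,
            alpha=cfg.alpha, seed=derive_seed(cfg.seed, f"decode1d-{kind}-paired"))
        union = None
        masks = [m for m in (_sig_time_window(vs_chance[c], times) for c in sim.TASKS)
                 if m is not None]
        if masks:
            union = np.logical_or.reduce(masks)
        results["decoding"][kind] = {
            "mean_accuracy": {c: float(curves[c].mean()) for c in sim.TASKS},
            "cluster_vs_chance": {c: _cluster_dict(vs_chance[c]) for c in sim.TASKS},
            "cluster_condition_contrast": _cluster_dict(paired),
            "interval_stats": _interval_stats(
                curves, times, union, cfg.decode_fallback_window_ms, 0.5,
                cfg.prior_scale),
        }

    # lateralization: pooled posterior 8-15 Hz index curves
    times = subj_stats[0]["lat_times_ms"]
    lcurves = {c: np.stack([st["lat_curves"][c] for st in subj_stats])
               for c in sim.TASKS}
    vs_zero = {
        c: cl.cluster_test_1d(
            lcurves[c], 0.0, n_permutations=cfg.n_permutations,
            cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
            seed=derive_seed(cfg.seed, f"lat1d-{c}"))
        for c in sim.TASKS}
    paired = cl.cluster_test_1d(
        lcurves["NCT"], paired_partner=lcurves["WMT"],
        n_permutations=cfg.n_permutations, cluster_alpha=cfg.cluster_alpha,
        alpha=cfg.alpha, seed=derive_seed(cfg.seed, "lat1d-paired"))
    masks = [m for m in (_sig_time_window(vs_zero[c], times) for c in sim.TASKS)
             if m is not None]
    union = np.logical_or.reduce(masks) if masks else None
    results["lateralization"] = {
        "cluster_vs_zero": {c: _cluster_dict(vs_zero[c]) for c in sim.TASKS},
        "cluster_condition_contrast": _cluster_dict(paired),
        "interval_stats": _interval_stats(
            lcurves, times, union, cfg.lat_fallback_window_ms, 0.0,
            cfg.prior_scale),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(to_json(results))
        (out / "summary.txt").write_text(render_summary(results))
        logger.info("results written to %s", out)
    return results


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg) if not isinstance(cfg.effects, sim.EffectSpec) else {
        **{f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)
           if f.name != "effects"},
        "effects": dataclasses.asdict(cfg.effects),
    }
    return json.loads(to_json(d))


def _cluster_dict(result: cl.ClusterTestResult, axes: dict | None = None) -> dict:
    d = {
        "n_clusters": len(result.clusters),
        "n_significant": len(result.significant),
        "n_permutations": result.n_permutations,
        "df": result.df,
        "clusters": [
            {"mass": c.mass, "p": c.p, "sign": c.sign, "n_pixels": c.n_pixels,
             "centroid": list(c.centroid())}
            for c in sorted(result.clusters, key=lambda c: c.p)
        ],
    }
    if axes:
        d["axes"] = axes
    return d


def to_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    return json.dumps(obj, sort_keys=True, indent=1, default=default)


def render_summary(results: dict) -> str:
    lines = ["task-prioritization synthetic pipeline summary", "=" * 47]
    b = results.get("behavior", {})
    for measure, stats in b.items():
        t = stats["paired_test"]
        lines.append(
            f"{measure}: NCT-imp {stats['mean']['NCT']:.2f} vs WMT-imp "
            f"{stats['mean']['WMT']:.2f}; t({t['df']}) = {t['t']:.2f}, "
            f"p = {t['p']:.3g}, d = {t['d']:.2f}, BF10 = {t['bf10']:.3g}")
    tc = results.get("tfr_cluster", {})
    lines.append(
        f"3-D power cluster test: {tc.get('n_significant', 0)} significant "
        f"of {tc.get('n_clusters', 0)} clusters")
    for kind, blk in results.get("decoding", {}).items():
        cc = blk["interval_stats"]["condition_contrast"]
        lines.append(
            f"decoding [{kind}]: mean acc NCT {blk['mean_accuracy']['NCT']:.3f} / "
            f"WMT {blk['mean_accuracy']['WMT']:.3f}; condition contrast "
            f"BF01 = {cc['bf01']:.3g}")
    lz = results.get("lateralization")
    if lz:
        cc = lz["interval_stats"]["condition_contrast"]
        vs = lz["interval_stats"]["vs_reference"]
        lines.append(
            f"lateralization: window mean NCT {vs['NCT']['mean']:.4f} "
            f"(BF10 {vs['NCT']['bf10']:.3g}) / WMT {vs['WMT']['mean']:.4f} "
            f"(BF10 {vs['WMT']['bf10']:.3g}); condition contrast BF01 = "
            f"{cc['bf01']:.3g}")
    return "\n".join(lines) + "\n"
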