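"""End-to-end orchestration: synthetic or file data through estimation,
scaling curves, Bayesian model fits, subspace decomposition, and tuning
classification, with text-table reporting.

The runnable surface of the package.  A flat key-value config file (or an
:class:`AnalysisConfig`) names the data source, the discrimination pairs,
estimator and bootstrap settings, and the MCMC preset; ``run_experiment``
produces a results bundle whose artifacts are stamped with the config hash
and master seed, and ``report`` renders it as a human-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import popsim, fisher, scaling, models, subspace, tuning

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "load_config",
    "run_experiment",
    "report",
    "NON_OVERLAPPING_45",
    "POOLED_PAIRS",
]

logger = logging.getLogger("infoscale")

# non-overlapping discrimination pairs (degrees) used for statistics
NON_OVERLAPPING_45 = ((0.0, 45.0), (90.0, 135.0), (180.0, 225.0), (270.0, 315.0))
# pooled estimates combine non-overlapping pairs at fixed delta-theta
POOLED_PAIRS = {
    45.0: ((45.0, 90.0), (135.0, 180.0), (225.0, 270.0), (315.0, 0.0)),
    90.0: ((45.0, 135.0), (90.0, 180.0), (225.0, 315.0), (0.0, 270.0)),
    135.0: ((45.0, 180.0), (90.0, 315.0), (0.0, 225.0)),
}
_PRESET_PAIRS = {
    "nonoverlap45": NON_OVERLAPPING_45,
    "pooled45": POOLED_PAIRS[45.0],
    "pooled90": POOLED_PAIRS[90.0],
    "pooled135": POOLED_PAIRS[135.0],
}

DEFAULT_CONDITIONS = tuple(float(x) for x in range(0, 360, 45))


@dataclass
class AnalysisConfig:
    """Settings for one end-to-end run.

    Either ``input_csv`` (a trial table written by
    :meth:`popsim.TrialDataset.to_csv`) or the synthetic-generator fields
    define the data source.  ``discriminations`` lists angle pairs in degrees
    or preset names ({"nonoverlap45", "pooled45", "pooled90", "pooled135"}).
    """

    # data source
    input_csv: str | None = None
    n_neurons: int = 60
    i_inf: float = 15.0
    sigma0_kind: str = "limited_range"
    trials_per_condition: int = 200
    conditions: tuple[float, ...] = DEFAULT_CONDITIONS
    # analysis
    discriminations: tuple = (("135.0", "180.0"),)
    pool: bool = True
    n_orderings: int = 1000
    n_boot: int = 1000
    families: tuple[str, ...] = ("unlim", "lim")
    mcmc_preset: str = "test"       # {"test", "paper"}
    mcmc_iters: int | None = None   # overrides the preset when set
    n_splits: int = 10
    run_subspace: bool = True
    run_tuning: bool = True
    # bookkeeping
    seed: int = 0
    output_dir: str | None = None

    def resolved_pairs(self) -> list[tuple[float, float]]:
        pairs: list[tuple[float, float]] = []
        for item in self.discriminations:
            if isinstance(item, str):
                if item not in _PRESET_PAIRS:
                    raise ValueError(f"unknown discrimination preset {item!r}")
                pairs.extend(_PRESET_PAIRS[item])
            else:
                pairs.append((float(item[0]), float(item[1])))
        return pairs

    def mcmc_config(self) -> models.MCMCConfig:
        cfg = models.MCMCConfig.paper() if self.mcmc_preset == "paper" else models.MCMCConfig.test()
        if self.mcmc_iters is not None:
            cfg.n_iter = int(self.mcmc_iters)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> AnalysisConfig:
    """Parse a flat ``key = value`` config file.

    Lists are comma-separated; discrimination pairs are ``theta1:theta2``
    items or preset names.  Lines starting with ``#`` are ignored.
    """
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()

    cfg = AnalysisConfig()
    casts = {
        "input_csv": str,
        "n_neurons": int,
        "i_inf": float,
        "sigma0_kind": str,
        "trials_per_condition": int,
        "pool": lambda s: s.lower() in ("1", "true", "yes"),
        "n_orderings": int,
        "n_boot": int,
        "mcmc_preset": str,
        "mcmc_iters": int,
        "n_splits": int,
        "run_subspace": lambda s: s.lower() in ("1", "true", "yes"),
        "run_tuning": lambda s: s.lower() in ("1", "true", "yes"),
        "seed": int,
        "output_dir": str,
    }
    for key, value in raw.items():
        if key == "conditions":
            cfg.conditions = tuple(float(x) for x in value.split(","))
        elif key == "discriminations":
            items = []
            for tok in value.split(","):
                tok = tok.strip()
                items.append(tuple(tok.split(":")) if ":" in tok else tok)
            cfg.discriminations = tuple(items)
        elif key == "families":
            cfg.families = tuple(f.strip() for f in value.split(","))
        elif key in casts:
            setattr(cfg, key, casts[key](value))
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


@dataclass
class ResultsBundle:
    """All computed artifacts of one run, stamped with config hash and seed."""

    config: AnalysisConfig
    config_hash: str
    seed: int
    discriminations: dict = field(default_factory=dict)  # label -> per-pair results
    pooled: dict = field(default_factory=dict)
    tuning_table: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _pair_label(t1: float, t2: float) -> str:
    return f"{t1:g}v{t2:g}"


def _fit_models(curves, families, mcmc, seed):
    """Fit each requested family; return fits, WAIC table, derived summaries."""
    fits, waic_table = {}, {}
    for fam in families:
        fit = models.fit_posterior(curves, family=fam, mcmc=mcmc, seed=seed)
        fits[fam] = fit
        waic_table[fam] = models.waic(fit)
    out = {"fits": fits, "waic": waic_table}
    if "lim" in fits:
        derived = models.derived_posteriors(fits["lim"], fraction=0.95)
        out["i_inf_summary"] = models.posterior_summary(derived["i_inf"])
        out["n95_summary"] = models.posterior_summary(derived["n_f"])
        out["psrf"] = models.psrf(fits["lim"])
    if {"lim", "unlim"} <= set(waic_table):
        out["limited_preferred"] = waic_table["lim"] < waic_table["unlim"]
    return out


def run_experiment(config: AnalysisConfig) -> ResultsBundle:
    """Run the full analysis described by ``config``.

    Stage failures are logged and recorded in ``bundle.errors``; completed
    stages are preserved.  Identical (config, seed) pairs produce identical
    bundles.
    """
    t_start = time.time()
    seed = int(config.seed)
    bundle = ResultsBundle(config=config, config_hash=config.config_hash(), seed=seed)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- data ---------------------------------------------------------
    if config.input_csv is not None:
        path = Path(config.input_csv)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        session = popsim.TrialDataset.from_csv(path)
        logger.info("loaded %s (%d conditions, %d neurons)", path, session.n_conditions, session.n_neurons)
    else:
        gen = popsim.PopulationConfig(
            n_neurons=config.n_neurons,
            i_inf=config.i_inf,
            sigma0_kind=config.sigma0_kind,
        )
        gt = popsim.make_population(gen, seed=seed)
        session = popsim.sample_session(
            gt, config.conditions, T=config.trials_per_condition, seed=seed + 1
        )
        logger.info("simulated session: %d neurons, %d conditions, T=%d", session.n_neurons, session.n_conditions, session.n_trials)

    pairs = config.resolved_pairs()
    mcmc = config.mcmc_config()
    curves_for_pooling = []

    for k, (t1, t2) in enumerate(pairs):
        label = _pair_label(t1, t2)
        t_stage = time.time()
        try:
            ds = session.select_pair(t1, t2)
            shuffled = popsim.shuffle_trials(ds, seed=seed + 100 + k)
            est = fisher.bias_corrected_info(ds)
            est_shuf = fisher.bias_corrected_info(shuffled)
            res = {
                "info": est,
                "info_shuffled": est_shuf,
                "threshold_deg": fisher.threshold_from_info(est.value) if est.value > 0 else None,
                # pr(I_shuffled - I_raw < 0): small p = significant gain from
                # removing noise correlations
                "p_shuffle_gain": scaling.info_difference_test(est_shuf, est),
            }
            curve = scaling.increment_curve(
                ds, n_orderings=config.n_orderings, seed=seed + 200 + k, label=label
            )
            res["curve"] = curve
            try:
                res["inverse_fit"] = models.inverse_scaling_fit(curve)
            except ValueError as err:  # weak sessions: too few positive <I_N>
                logger.warning("inverse-information fit skipped for %s: %s", label, err)
            res.update(_fit_models([curve], config.families, mcmc, seed + 300 + k))
            size, ci = scaling.capture_size(curve, fraction=0.9)
            res["capture90"] = {"size": size, "ci": ci}
            if config.run_subspace:
                splits = subspace.split_pca(ds, n_splits=config.n_splits, seed=seed + 400 + k)
                summary = subspace.subspace_summary(splits)
                res["subspace"] = subspace.fraction_to_threshold(summary, level=0.9)
            curves_for_pooling.append(curve)
            bundle.discriminations[label] = res
            if out_dir is not None:
                curve.to_csv(out_dir / f"curve_{label}.tsv")
                if "lim" in res.get("fits", {}):
                    res["fits"]["lim"].to_frame().to_csv(
                        out_dir / f"posterior_lim_{label}.tsv", sep="\t", index=False
                    )
            logger.info("discrimination %s done in %.1fs", label, time.time() - t_stage)
        except Exception as err:  # keep partial results
            logger.exception("discrimination %s failed", label)
            bundle.errors.append(f"{label}: {err}")

    if config.pool and len(curves_for_pooling) > 1:
        try:
            same_dt = [
                c for c in curves_for_pooling
                if np.isclose(c.delta_theta, curves_for_pooling[0].delta_theta)
            ]
            bundle.pooled = _fit_models(same_dt, config.families, mcmc, seed + 999)
            bundle.pooled["n_curves"] = len(same_dt)
        except Exception as err:
            logger.exception("pooled fit failed")
            bundle.errors.append(f"pooled: {err}")

    if config.run_tuning:
        try:
            n_neurons = session.n_neurons
            n_tests = 2 * n_neurons  # Bonferroni: two cascade tests per neuron
            n_obs = session.n_trials * session.n_conditions
            labels = []
            for j in range(n_neurons):
                resp = [r[:, j] for r in session.responses]
                fits = tuning.fit_tuning(session.conditions, resp)
                labels.append(tuning.classify_neuron(fits, n_obs=n_obs, n_tests=n_tests))
            labels = np.asarray(labels)
            cvs = [
                tuning.coefficient_of_variation([r[:, j] for r in session.responses])
                for j in range(n_neurons)
                if labels[j] != "untuned"
            ]
            bundle.tuning_table = {
                "labels": labels.tolist(),
                "counts": {lab: int((labels == lab).sum()) for lab in ("direction", "orientation", "untuned")},
                "mean_cv_tuned": float(np.nanmean(cvs)) if cvs else None,
            }
        except Exception as err:
            logger.exception("tuning classification failed")
            bundle.errors.append(f"tuning: {err}")

    if out_dir is not None:
        (out_dir / "report.txt").write_text(report(bundle))
        (out_dir / "summary.json").write_text(json.dumps(_json_summary(bundle), indent=2))
    logger.info("experiment finished in %.1fs (%d errors)", time.time() - t_start, len(bundle.errors))
    return bundle


def _summary_line(name: str, s: dict) -> str:
    return (
        f"{name}: median {s['median']:.4g}, "
        f"50% CI [{s['ci50'][0]:.4g}, {s['ci50'][1]:.4g}], "
        f"90% CI [{s['ci90'][0]:.4g}, {s['ci90'][1]:.4g}]"
    )


def _json_summary(bundle: ResultsBundle) -> dict:
    out = {"config_hash": bundle.config_hash, "seed": bundle.seed, "errors": bundle.errors}
    for label, res in bundle.discriminations.items():
        d = {
            "info": res["info"].value,
            "info_sd": res["info"].sd,
            "info_shuffled": res["info_shuffled"].value,
            "p_shuffle_gain": res["p_shuffle_gain"],
            "waic": res.get("waic"),
            "limited_preferred": res.get("limited_preferred"),
            "inverse_fit": res.get("inverse_fit"),
            "capture90": {"size": res["capture90"]["size"], "ci": list(res["capture90"]["ci"]) if res["capture90"]["ci"] else None} if "capture90" in res else None,
        }
        if "i_inf_summary" in res:
            d["i_inf"] = res["i_inf_summary"]
            d["n95"] = res["n95_summary"]
        if "subspace" in res:
            d["subspace"] = {k: v for k, v in res["subspace"].items() if k != "per_split"}
        out.setdefault("discriminations", {})[label] = d
    if bundle.pooled:
        out["pooled"] = {
            "waic": bundle.pooled.get("waic"),
            "i_inf": bundle.pooled.get("i_inf_summary"),
            "n95": bundle.pooled.get("n95_summary"),
        }
    if bundle.tuning_table:
        out["tuning"] = {k: v for k, v in bundle.tuning_table.items() if k != "labels"}
    return out


def report(bundle: ResultsBundle) -> str:
    """Human-readable summary of a results bundle.

    Regenerable byte-identically from the same bundle; posterior summary
    lines always print median, 50% CI, 90% CI in that order.
    """
    lines = [
        "information scaling analysis report",
        f"config hash: {bundle.config_hash}   seed: {bundle.seed}",
        "",
    ]
    for label, res in sorted(bundle.discriminations.items()):
        est = res["info"]
        lines.append(f"== discrimination {label} (delta-theta {np.rad2deg(est.delta_theta):.0f} deg) ==")
        lines.append(
            f"  information: {est.value:.4g} +- {est.sd:.3g} rad^-2 "
            f"(N={est.n_neurons}, T={est.n_trials})"
        )
        lines.append(
            f"  trial-shuffled: {res['info_shuffled'].value:.4g} rad^-2 "
            f"(p[no shuffle gain] = {res['p_shuffle_gain']:.3g})"
        )
        if res.get("threshold_deg") is not None:
            lines.append(f"  80%-correct threshold: {res['threshold_deg']:.3g} deg")
        if "waic" in res:
            table = ", ".join(f"{fam}: {w:.2f}" for fam, w in res["waic"].items())
            lines.append(f"  WAIC (smaller is better): {table}")
            if res.get("limited_preferred") is True:
                lines.append("  model comparison: limited asymptotic information preferred")
            elif res.get("limited_preferred") is False:
                lines.append("  model comparison: no evidence of limited information")
        if "inverse_fit" in res:
            iv = res["inverse_fit"]
            lines.append(
                f"  1/I vs 1/N: slope {iv['slope']:.4g}, intercept {iv['intercept']:.4g} "
                f"(R^2 {iv['r_squared']:.4f}, one-sided p {iv['intercept_pvalue']:.3g})"
            )
        if "i_inf_summary" in res:
            lines.append("  " + _summary_line("I_inf (rad^-2)", res["i_inf_summary"]))
            lines.append("  " + _summary_line("N_95 (neurons)", res["n95_summary"]))
        if "capture90" in res:
            ci = res["capture90"]["ci"]
            ci_txt = f" (95% CI {ci[0]}-{ci[1]})" if ci else ""
            lines.append(f"  neurons for 90% of recorded info: {res['capture90']['size']}{ci_txt}")
        if "subspace" in res:
            sub = res["subspace"]
            lines.append(
                "  dims for 90%: variance "
                f"{sub['variance']:.1%}, alignment {sub['alignment']:.1%}, "
                f"information {sub['information']:.1%}"
            )
        lines.append("")
    if bundle.pooled:
        lines.append(f"== pooled fit ({bundle.pooled.get('n_curves', 0)} curves) ==")
        if "waic" in bundle.pooled:
            table = ", ".join(f"{fam}: {w:.2f}" for fam, w in bundle.pooled["waic"].items())
            lines.append(f"  WAIC: {table}")
        if "i_inf_summary" in bundle.pooled:
            lines.append("  " + _summary_line("I_inf (rad^-2)", bundle.pooled["i_inf_summary"]))
            lines.append("  " + _summary_line("N_95 (neurons)", bundle.pooled["n95_summary"]))
        lines.append("")
    if bundle.tuning_table:
        counts = bundle.tuning_table["counts"]
        total = sum(counts.values())
        lines.append("== tuning classification ==")
        lines.append(
            "  " + ", ".join(f"{k}: {v} ({v / total:.0%})" for k, v in counts.items())
        )
        if bundle.tuning_table.get("mean_cv_tuned") is not None:
            lines.append(f"  mean CV of tuned neurons: {bundle.tuning_table['mean_cv_tuned']:.3g}")
        lines.append("")
    if bundle.errors:
        lines.append("== incomplete stages ==")
        lines.extend(f"  {e}" for e in bundle.errors)
        lines.append("")
    return "\n".join(lines)
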