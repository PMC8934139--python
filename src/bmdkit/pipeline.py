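"""End-to-end orchestration: screen -> fit -> BMD -> pathway, with
deterministic seeding, config hashing, and comparison-ready report tables.

The unit of work is :func:`fit_probe`: fit the selected dose-response models
to one probe by MCMC, estimate posterior model weights, transform every draw
into a BMD, and mix the per-model BMD samples into the model-averaged
posterior. :func:`run_pipeline` applies this over a dataset behind a
:class:`RunConfig`, writing CSV outputs that each carry the config hash so a
run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .bayes import McmcSettings, estimate_model_weights, model_average_draws, \
    sample_posterior
from .bmd import DEFAULT_CAP_FACTOR, BmdEstimate, BmrSpec, bmd_draws, \
    summarize_bmd
from .data_io import ExpressionDataset, read_dose_map, \
    read_expression_matrix, read_gmt, read_probe_map, summarize_dataset
from .models import MODEL_IDS, ModelSpec, PriorConfig
from .pathway import pathway_analysis
from .preprocess import FilterSettings, screen_probes

logger = logging.getLogger("bmdkit")

__all__ = ["RunConfig", "PipelineResult", "fit_probe", "fit_dataset",
           "run_pipeline", "comparison_report", "trend_direction"]


def trend_direction(x: np.ndarray, y: np.ndarray) -> int:
    """Adversity direction from the data: sign of (top-dose mean - control
    mean); ties resolve to increasing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    delta = y[x == x.max()].mean() - y[x == x.min()].mean()
    return -1 if delta < 0 else +1


def fit_probe(x: np.ndarray, y: np.ndarray, model_ids=MODEL_IDS,
              settings: McmcSettings | None = None,
              bmr: BmrSpec | None = None, probe_id: str = "",
              prior_weights=None, bma_draws: int = 2000,
              cap_factor: float = DEFAULT_CAP_FACTOR,
              keep_model_draws: bool = True) -> BmdEstimate:
    """Model-averaged BMD estimation for one probe.

    ``x`` are doses in native units; ``y`` the log-scale responses. Doses are
    rescaled by the maximum dose for fitting and BMD draws rescaled back, so
    the returned estimate is in dose units.
    """
    settings = settings or McmcSettings()
    bmr = bmr or BmrSpec("sd_shift", 1.0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    max_dose = float(x.max())
    xs = x / max_dose
    direction = trend_direction(x, y)
    priors = PriorConfig.from_data(xs, y)

    fits = []
    per_model_bmd = {}
    flagged = []
    for j, mid in enumerate(model_ids):
        spec = ModelSpec(mid, direction, priors)
        msettings = McmcSettings(settings.iterations, settings.chains,
                                 settings.warmup_fraction,
                                 (settings.seed + 104729 * (j + 1)) % (2 ** 31))
        fit = sample_posterior(spec, xs, y, msettings)
        fits.append(fit)
        per_model_bmd[mid] = bmd_draws(spec, fit.draws, bmr, max_dose, cap_factor)
        if not fit.diagnostics.get("converged", True):
            flagged.append(mid)
    weights = estimate_model_weights(fits, prior_weights)
    averaged = model_average_draws(per_model_bmd,
                                   {m: w for m, w in zip(model_ids, weights)},
                                   total_draws=bma_draws,
                                   seed=(settings.seed + 65537) % (2 ** 31))
    bmd, bmdl, bmdu = summarize_bmd(averaged)
    cap = cap_factor * max_dose
    capped = float(np.mean(averaged >= cap * (1 - 1e-9)))
    return BmdEstimate(
        probe_id=probe_id,
        model_draws=per_model_bmd if keep_model_draws else {},
        averaged_draws=averaged,
        bmd=bmd, bmdl=bmdl, bmdu=bmdu,
        weights={m: float(w) for m, w in zip(model_ids, weights)},
        above_max_dose=bool(bmd > max_dose),
        quality={"capped_fraction": capped, "flagged_models": flagged},
    )


def fit_dataset(ds: ExpressionDataset, probe_ids=None, model_ids=MODEL_IDS,
                settings: McmcSettings | None = None,
                bmr: BmrSpec | None = None, bma_draws: int = 2000,
                keep_draws: bool = False):
    """Fit every (requested) probe of a dataset; returns the per-probe BMD
    table and, optionally, the :class:`BmdEstimate` objects."""
    settings = settings or McmcSettings()
    probe_ids = list(probe_ids) if probe_ids is not None else list(ds.probe_ids)
    seeds = np.random.SeedSequence(settings.seed).spawn(len(probe_ids))
    rows, estimates = [], []
    for probe, seed in zip(probe_ids, seeds):
        child = int(seed.generate_state(1)[0] % (2 ** 31))
        est = fit_probe(ds.doses, ds.probe_values(probe), model_ids,
                        McmcSettings(settings.iterations, settings.chains,
                                     settings.warmup_fraction, child),
                        bmr, probe_id=probe, bma_draws=bma_draws,
                        keep_model_draws=keep_draws)
        row = {"probe_id": probe, "bmd": est.bmd, "bmdl": est.bmdl,
               "bmdu": est.bmdu, "above_max_dose": est.above_max_dose,
               "capped_fraction": est.quality["capped_fraction"],
               "flagged_models": ";".join(est.quality["flagged_models"])}
        row.update({f"w_{m}": w for m, w in est.weights.items()})
        rows.append(row)
        if keep_draws:
            estimates.append(est)
    table = pd.DataFrame(rows)
    return (table, estimates) if keep_draws else (table, None)


# -- configuration -----------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration; serializes to/from YAML and hashes canonically.

    ``simulate`` (a dict of :func:`bmdkit.synthetic.simulate_experiment`
    keyword arguments) and the file inputs (``matrix``/``doses``) are mutually
    exclusive. Every stochastic stage derives its seed from ``seed``.
    """

    seed: int = 0
    outdir: str = "bmdkit_run"
    simulate: dict | None = None
    matrix: str | None = None
    doses: str | None = None
    log_base: float | str = 2
    probe_map: str | None = None
    gmt: str | None = None
    models: tuple = MODEL_IDS
    iterations: int = 30000
    chains: int = 1
    warmup_fraction: float = 0.5
    bmr: str = "sd:1"
    bma_draws: int = 2000
    fold_change_cutoff: float = 2.0
    p_cutoff: float = 0.05
    which_test: str = "williams"
    use_adjusted: bool = False
    resampling_count: int = 1000
    pathway_p_cutoff: float = 0.05
    pathway_min_genes: int = 1
    pathway_min_percentage: float = 0.03
    run_pathway: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.models = tuple(cfg.models)
        return cfg


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: ExpressionDataset
    screen: pd.DataFrame
    bmd_table: pd.DataFrame
    pathway_table: pd.DataFrame | None
    bepod: object
    truth: object = None
    paths: dict = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}  bmdkit {_version}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline described by ``config``.

    Stages: load/simulate -> validity summary -> probe screen -> per-probe
    model-averaged BMD -> pathway enrichment and BEPOD. Outputs are written to
    ``config.outdir`` with the config hash in every file header; identical
    configs reproduce identical files.
    """
    annotation = None
    truth = None
    if config.simulate is not None:
        from .synthetic import simulate_experiment
        kwargs = dict(config.simulate)
        kwargs.setdefault("seed", config.seed)
        gen_bmr = kwargs.get("bmr")
        if isinstance(gen_bmr, str):
            kwargs["bmr"] = BmrSpec.parse(gen_bmr)
        elif isinstance(gen_bmr, dict):
            kwargs["bmr"] = BmrSpec(**gen_bmr)
        ds, truth, annotation = simulate_experiment(**kwargs)
    else:
        if not (config.matrix and config.doses):
            raise ValueError("config needs either 'simulate' or 'matrix'+'doses'")
        ds = read_expression_matrix(config.matrix, read_dose_map(config.doses),
                                    config.log_base)
        if config.probe_map and config.gmt:
            annotation = read_gmt(config.gmt)
            annotation.probe_to_genes = read_probe_map(config.probe_map)
    if config.run_pathway and annotation is None:
        raise ValueError("pathway stage enabled but probe map/GMT inputs are "
                         "missing (pre-flight check)")

    chash = config.config_hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary = summarize_dataset(ds)
    logger.info("dataset: %d probes (%d valid), %d dose levels",
                ds.n_probes, summary.n_valid_probes, summary.n_dose_levels)

    fsettings = FilterSettings(config.fold_change_cutoff, config.p_cutoff,
                               config.which_test, config.use_adjusted,
                               config.resampling_count, config.seed)
    screen = screen_probes(ds, fsettings)
    kept = screen.loc[screen["passed"], "probe_id"].tolist()
    logger.info("screen: %d of %d probes pass", len(kept), ds.n_probes)

    msettings = McmcSettings(config.iterations, config.chains,
                             config.warmup_fraction, config.seed)
    bmr = BmrSpec.parse(config.bmr)
    bmd_table, _ = fit_dataset(ds, kept, tuple(config.models), msettings, bmr,
                               config.bma_draws)
    logger.info("fit: %d probes modeled with %d models",
                len(bmd_table), len(config.models))

    pathway_table, bepod = None, None
    if config.run_pathway and len(bmd_table):
        pathway_table, bepod = pathway_analysis(
            bmd_table, annotation, config.pathway_p_cutoff,
            config.pathway_min_genes, config.pathway_min_percentage)
        logger.info("pathway: %d categories, BEPOD=%s",
                    len(pathway_table), bepod.bepod)

    paths = {"screen": outdir / "screen.csv", "bmd": outdir / "bmd.csv"}
    _write_csv(screen, paths["screen"], chash)
    _write_csv(bmd_table, paths["bmd"], chash)
    if len(bmd_table):
        from .bmd import bmd_ratio_stats
        paths["ratios"] = outdir / "ratios.csv"
        _write_csv(bmd_ratio_stats(bmd_table), paths["ratios"], chash)
    if pathway_table is not None:
        paths["pathway"] = outdir / "pathway.csv"
        _write_csv(pathway_table, paths["pathway"], chash)
        paths["bepod"] = outdir / "bepod.csv"
        _write_csv(pd.DataFrame([{
            "bepod": bepod.bepod,
            "n_enriched": len(bepod.enriched_categories),
            "enriched_categories": ";".join(bepod.enriched_categories)}]),
            paths["bepod"], chash)
    config.to_yaml(outdir / "config.yaml")
    return PipelineResult(config, ds, screen, bmd_table, pathway_table, bepod,
                          truth, {k: str(v) for k, v in paths.items()})


def comparison_report(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      max_dose: float | None = None) -> pd.DataFrame:
    """Cross-run comparison of BMD tables sharing probe ids.

    Reports, for BMD and BMDL: the median and central 95% interval of the
    per-probe ratio (run A / run B) and the Pearson correlation of the log10
    estimates — once over all shared probes and, when ``max_dose`` is given,
    once excluding probes whose run-A BMD exceeds the maximum dose.
    """
    merged = table_a.merge(table_b, on="probe_id", suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("no shared probes between the two tables")

    def _stats(df, label):
        rows = []
        for q in ("bmd", "bmdl"):
            ratio = df[f"{q}_a"] / df[f"{q}_b"]
            lo, med, hi = np.percentile(ratio, [2.5, 50, 97.5])
            r = np.corrcoef(np.log10(df[f"{q}_a"]), np.log10(df[f"{q}_b"]))[0, 1]
            rows.append({"subset": label, "quantity": q, "n": len(df),
                         "ratio_median": med, "ratio_p2.5": lo,
                         "ratio_p97.5": hi, "pearson_r_log10": r})
        return rows

    rows = _stats(merged, "all")
    if max_dose is not None:
        sub = merged[merged["bmd_a"] <= max_dose]
        if len(sub):
            rows += _stats(sub, "within_max_dose")
    return pd.DataFrame(rows)
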