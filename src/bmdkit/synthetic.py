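"""Synthetic dose-response experiments with known ground truth.

The generator emulates the multi-dose toxicogenomic designs this pipeline is
built for: a small number of dose levels (default 5: control plus four
geometrically spaced doses), a handful of replicates per level (default 4),
and log2-scale expression values with microarray-like backgrounds and
residual noise. Responsive probes are drawn from the seven-model mix with
their parameters solved so that the *true* BMD under a stated BMR lands at a
chosen point of the dose axis (by default log-uniform between 0.1x and 2x the
maximum dose, so the above-maximum-dose path is exercised); null probes are
pure noise around a flat background.

A companion annotation maps each probe to a gene and groups genes into
categories such that one designed category is dominated by responsive genes
(the enrichment ground truth) while the others are background.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bmd import BmrSpec, bmd_from_draw
from .data_io import ExpressionDataset, GeneAnnotation
from .models import MODEL_IDS, ModelSpec, predict

__all__ = ["SimTruth", "simulate_probe", "solve_theta_for_bmd",
           "simulate_experiment", "DEFAULT_DOSES", "RESPONSIVE_CATEGORY"]

DEFAULT_DOSES = (0.0, 12.5, 25.0, 50.0, 100.0)
RESPONSIVE_CATEGORY = "CAT_RESP"


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``probes`` is a per-probe table (probe_id, responsive, model_id,
    direction, sigma, true_bmd, theta as JSON); ``doses``/``n_per_dose``/
    ``seed``/``bmr`` record the design; ``category_composition`` counts
    responsive genes per category.
    """

    probes: pd.DataFrame
    doses: tuple
    n_per_dose: int
    seed: int
    bmr: BmrSpec
    category_composition: dict = field(default_factory=dict)

    def true_bmd(self, probe_id: str) -> float:
        row = self.probes.set_index("probe_id").loc[probe_id]
        return float(row["true_bmd"])

    def to_csv(self, path) -> None:
        self.probes.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, doses, n_per_dose, seed, bmr) -> "SimTruth":
        return cls(pd.read_csv(path), tuple(doses), n_per_dose, seed, bmr)


def simulate_probe(model_id: str, theta, sigma: float, doses, n_per_dose: int,
                   seed: int, direction: int = +1,
                   bmr: BmrSpec | None = None):
    """Simulate one probe's responses y ~ Normal(f(x | theta), sigma).

    ``theta`` is on the rescaled dose axis (x = dose / max dose). Returns
    ``(y, x_doses, true_bmd)`` where ``true_bmd`` (dose units) is computed by
    the same algebra the estimation side uses.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    bmr = bmr or BmrSpec("sd_shift", 1.0)
    doses = np.asarray(doses, dtype=float)
    max_dose = doses.max()
    x_samples = np.repeat(doses, n_per_dose)
    spec = ModelSpec(model_id, direction)
    mu = predict(spec, np.asarray(theta, dtype=float), x_samples / max_dose)
    rng = np.random.default_rng(seed)
    y = mu + sigma * rng.standard_normal(x_samples.size)
    draw = np.concatenate([np.asarray(theta, dtype=float), [max(sigma, 1e-12)]])
    true_bmd = bmd_from_draw(spec, draw, bmr, max_dose=max_dose)
    return y, x_samples, true_bmd


def solve_theta_for_bmd(model_id: str, target_x: float, amount: float,
                        a: float, direction: int, rng) -> np.ndarray:
    """Pick model parameters whose curve crosses the BMR amount exactly at
    ``target_x`` (rescaled dose units): shapes are drawn, the rate/increment
    parameter is solved analytically."""
    t, A = float(target_x), float(amount)
    if model_id == "linear":
        return np.array([a, A / t])
    if model_id == "power":
        g_hi = 3.0
        if t < 1.0:
            # bound the top-dose change A * t**-g to ~20 log units
            g_hi = min(3.0, max(1.0, math.log(20.0 / A) / math.log(1.0 / t)))
        g = rng.uniform(1.0, g_hi)
        return np.array([a, A / t ** g, g])
    if model_id == "hill":
        g = rng.uniform(1.0, 3.0)
        # half-maximal dose near the target keeps the plateau b = A(1+(c/t)^g)
        # within a plausible expression range
        c = float(np.clip(t * rng.uniform(0.5, 2.0), 0.05, 1.5))
        b = A * (c ** g + t ** g) / t ** g
        return np.array([a, b, c, g])
    if model_id in ("exp2", "exp3"):
        core = math.log1p(A / a) if direction > 0 else -math.log1p(-min(A / a, 0.999))
        if model_id == "exp2":
            return np.array([a, core / t])
        g_hi = 3.0
        if direction > 0 and t < 1.0:
            # keep the top-dose exponent core * t**-g below ~3 so increasing
            # exponential curves stay in a plausible expression range
            g_hi = min(3.0, max(1.0, math.log(3.0 / core) / math.log(1.0 / t)))
        g = rng.uniform(1.0, g_hi)
        return np.array([a, core ** (1.0 / g) / t, g])
    if model_id in ("exp4", "exp5"):
        c = 1.0 + rng.uniform(0.2, 1.0) if direction > 0 else rng.uniform(0.3, 0.8)
        q = A / (a * abs(c - 1.0))
        if q >= 1.0:  # plateau too low for this amount; raise the plateau
            c = 1.0 + 2.0 * q if direction > 0 else max(1.0 - 2.0 * q, 1e-3)
            q = A / (a * abs(c - 1.0))
        core = -math.log1p(-min(q, 0.999))
        if model_id == "exp4":
            return np.array([a, core / t, c])
        g = rng.uniform(1.0, 3.0)
        return np.array([a, core ** (1.0 / g) / t, c, g])
    raise ValueError(f"unknown model {model_id!r}")


def simulate_experiment(n_probes: int = 100, responsive_fraction: float = 0.2,
                        model_mix=None, doses=DEFAULT_DOSES, n_per_dose: int = 4,
                        seed: int = 0, sigma: float = 0.25,
                        bmr: BmrSpec | None = None,
                        bmd_range: tuple = (0.1, 2.0),
                        background_range: tuple = (6.0, 10.0),
                        n_categories: int = 8, category_size: int = 15,
                        n_multigene_probes: int | None = None,
                        log_base: float = 2.0):
    """Generate a full experiment: expression matrix, ground truth, annotation.

    ``bmd_range`` positions true BMDs log-uniformly as multiples of the
    maximum dose. ``model_mix`` maps model ids to sampling probabilities
    (default uniform over the seven models). Returns
    ``(ExpressionDataset, SimTruth, GeneAnnotation)``.
    """
    if not (0.0 <= responsive_fraction <= 1.0):
        raise ValueError("responsive_fraction must lie in [0, 1]")
    bmr = bmr or BmrSpec("sd_shift", 1.0)
    if model_mix is None:
        model_mix = {m: 1.0 / len(MODEL_IDS) for m in MODEL_IDS}
    mix_ids = list(model_mix)
    mix_p = np.array([model_mix[m] for m in mix_ids], dtype=float)
    mix_p = mix_p / mix_p.sum()

    doses = np.asarray(doses, dtype=float)
    max_dose = doses.max()
    rng = np.random.default_rng(seed)
    n_responsive = int(round(responsive_fraction * n_probes))
    responsive = np.zeros(n_probes, dtype=bool)
    responsive[rng.choice(n_probes, size=n_responsive, replace=False)] = True

    x_samples = np.repeat(doses, n_per_dose)
    values = np.empty((n_probes, x_samples.size))
    rows = []
    for i in range(n_probes):
        probe = f"p{i:05d}"
        a = rng.uniform(*background_range)
        if responsive[i]:
            model_id = mix_ids[rng.choice(len(mix_ids), p=mix_p)]
            direction = +1 if rng.random() < 0.5 else -1
            lo, hi = bmd_range
            t = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            if bmr.kind == "sd_shift":
                amount = bmr.value * sigma
            else:
                amount = bmr.value * a
            theta = solve_theta_for_bmd(model_id, t, amount, a, direction, rng)
            spec = ModelSpec(model_id, direction)
            mu = predict(spec, theta, x_samples / max_dose)
            true_bmd = bmd_from_draw(spec, np.concatenate([theta, [max(sigma, 1e-12)]]),
                                     bmr, max_dose=max_dose)
        else:
            model_id, direction, theta, true_bmd = "", 0, np.array([a]), np.nan
            mu = np.full(x_samples.size, a)
        values[i] = mu + sigma * rng.standard_normal(x_samples.size)
        rows.append({"probe_id": probe, "responsive": bool(responsive[i]),
                     "model_id": model_id, "direction": direction,
                     "sigma": sigma, "true_bmd": true_bmd,
                     "theta": json.dumps(np.round(theta, 12).tolist())})
    truth_df = pd.DataFrame(rows)

    sample_ids = [f"d{j}_r{k}" for j, d in enumerate(doses) for k in range(n_per_dose)]
    ds = ExpressionDataset(truth_df["probe_id"].tolist(), values, x_samples,
                           log_base, sample_ids, dose_units="arb. units")

    annotation = _build_annotation(truth_df, rng, n_categories, category_size,
                                   n_multigene_probes)
    composition = {cid: sum(g in set(truth_df.loc[truth_df.responsive, "probe_id"]
                                     .str.replace("p", "g", regex=False))
                            for g in genes)
                   for cid, (_, genes) in annotation.categories.items()}
    truth = SimTruth(truth_df, tuple(doses), n_per_dose, seed, bmr, composition)
    return ds, truth, annotation


def _build_annotation(truth_df, rng, n_categories, category_size, n_multigene):
    probes = truth_df["probe_id"].tolist()
    genes = [p.replace("p", "g", 1) for p in probes]
    probe_to_genes = {p: {g} for p, g in zip(probes, genes)}
    if n_multigene is None:
        n_multigene = max(1, len(probes) // 50)
    # the last null probes double-map to a second gene -> removed in mapping
    null_probes = truth_df.loc[~truth_df.responsive, "probe_id"].tolist()
    for p in null_probes[-n_multigene:]:
        probe_to_genes[p] = {p.replace("p", "g", 1), p.replace("p", "gx", 1)}

    # the designed category takes the earliest responders (lowest true BMD);
    # leftover responsive genes mix into the background pool the way real
    # pathways share stray responsive members
    resp = truth_df[truth_df.responsive].sort_values("true_bmd")
    resp_genes = [p.replace("p", "g", 1) for p in resp["probe_id"]]
    null_genes = [g for g, r in zip(genes, truth_df["responsive"]) if not r]
    categories = {}
    take = min(category_size, len(resp_genes))
    members = list(resp_genes[:take])
    pad = category_size - take
    if pad > 0 and null_genes:
        members += list(rng.choice(null_genes, size=min(pad, len(null_genes)),
                                   replace=False))
    if members:
        categories[RESPONSIVE_CATEGORY] = ("designed responsive category",
                                           set(members))
    pool = resp_genes[take:] + null_genes
    pool = pool if pool else genes
    for c in range(1, n_categories):
        size = min(category_size, len(pool))
        if size == 0:
            break
        picked = rng.choice(pool, size=size, replace=False)
        categories[f"CAT_BG{c:02d}"] = (f"background category {c}", set(picked))
    return GeneAnnotation(probe_to_genes=probe_to_genes, categories=categories,
                          source_label="synthetic")


def write_bundle(ds: ExpressionDataset, truth: SimTruth,
                 annotation: GeneAnnotation, outdir) -> dict:
    """Write matrix, dose map, probe map, GMT and truth table to a directory."""
    from pathlib import Path

    from .data_io import write_expression_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "doses": outdir / "doses.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "gmt": outdir / "categories.gmt",
        "truth": outdir / "truth.csv",
    }
    write_expression_matrix(ds, paths["matrix"])
    with open(paths["doses"], "w") as fh:
        fh.write("sample_id\tdose\n")
        for s, d in zip(ds.sample_ids, ds.doses):
            fh.write(f"{s}\t{d:g}\n")
    with open(paths["probe_map"], "w") as fh:
        for p, gs in annotation.probe_to_genes.items():
            for g in sorted(gs):
                fh.write(f"{p}\t{g}\n")
    with open(paths["gmt"], "w") as fh:
        for cid, (name, gs) in annotation.categories.items():
            fh.write("\t".join([cid, name] + sorted(gs)) + "\n")
    truth.to_csv(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
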