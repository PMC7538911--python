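"""Pipeline stages over a run directory.

Each stage reads and writes plain-text artifacts inside one run directory
and records a manifest (command, config, config hash, seed, package
version) so that every artifact is traceable and deterministic stages are
bit-reproducible.  The conventional layout of a full run:

    faces.csv                          exp-1 face population
    ratings_<task>.csv                 exp-1 rating trials (long format)
    truth.json                         generator ground truth (for checks)
    direction_<task>.json              fitted + scaled trait directions
    direction_attr_orth.json           attractiveness orthogonal to dimorphism
    direction_masc_orth.json           dimorphism orthogonal to attractiveness
    stimuli_exp2.csv                   280 transformed validation faces
    trials_<task>_<transform>.csv      exp-2 rating trials per cell
    validate_<task>_<transform>/       posterior summaries per cell
    compare_table.csv                  generated-quantity contrasts
    report.txt                         dissociation summary
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError
from .face_space import TransformSpec, read_faces, transform_faces, write_faces
from .hier_model import (
    MCMCConfig,
    ModelSpec,
    PosteriorSummary,
    candidate_specs,
    fit_hierarchical,
    select_best,
    waic_detail,
)
from .synthetic_data import (
    GroundTruth,
    SimConfig,
    make_ground_truth,
    sample_faces,
    simulate_experiment2,
    simulate_ratings,
)
from .trait_model import (
    TraitDirection,
    orthogonalize,
    fit_trait_direction,
    ratings_to_matrix,
    read_ratings,
    scale_to_sd_units,
    standardize_scores_by_face_sex,
    write_ratings,
)

TASKS = ("attractiveness", "sexual_dimorphism")
TRANSFORMS = ("attr_orth", "masc_orth")
EXP2_CELLS = [(task, tr) for task in TASKS for tr in TRANSFORMS]


def _write_manifest(run_dir: Path, command: str, config: dict) -> dict:
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()
    manifest = {
        "command": command,
        "run_id": digest[:12],
        "config": config,
        "config_hash": digest,
        "package_version": __version__,
    }
    (run_dir / f"manifest_{command}.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _truth_from_json(path: Path) -> GroundTruth:
    d = json.loads(path.read_text())
    return GroundTruth(
        beta_attr=np.asarray(d.pop("beta_attr"), float),
        beta_masc=np.asarray(d.pop("beta_masc"), float),
        **d,
    )


def stage_simulate(
    run_dir: str | Path,
    seed: int = 0,
    cos_angle: float = -0.4,
    n_faces: int = 400,
    n_raters: int = 20,
) -> dict:
    """Generate the model-building population and both rating tasks."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    truth = make_ground_truth(cos_angle=cos_angle, seed=seed)
    faces = sample_faces(n_faces, seed=seed + 1)
    write_faces(faces, run_dir / "faces.csv")
    (run_dir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
    for k, direction in enumerate(("attr", "masc")):
        _, trials = simulate_ratings(
            faces, truth, direction, n_raters=n_raters, seed=seed + 2 + k
        )
        write_ratings(trials, run_dir / f"ratings_{trials['task'].iloc[0]}.csv")
    return _write_manifest(
        run_dir,
        "simulate",
        {
            "seed": seed,
            "cos_angle": cos_angle,
            "n_faces": n_faces,
            "n_raters": n_raters,
        },
    )


def stage_build(
    run_dir: str | Path, task: str, sex_policy: str = "pooled"
) -> TraitDirection:
    """Fit and SD-scale one trait direction from the exp-1 ratings."""
    run_dir = Path(run_dir)
    faces = read_faces(run_dir / "faces.csv")
    trials = read_ratings(run_dir / f"ratings_{task}.csv")
    matrix = ratings_to_matrix(trials)
    scores = standardize_scores_by_face_sex(matrix)
    direction = scale_to_sd_units(fit_trait_direction(faces, scores, sex_policy))
    direction.save(run_dir / f"direction_{task}.json")
    _write_manifest(run_dir, f"build_{task}", {"task": task, "sex_policy": sex_policy})
    return direction


def stage_orthogonalize(run_dir: str | Path) -> dict[str, TraitDirection]:
    """Orthogonalize each fitted direction against the other."""
    run_dir = Path(run_dir)
    attr = TraitDirection.load(run_dir / "direction_attractiveness.json")
    masc = TraitDirection.load(run_dir / "direction_sexual_dimorphism.json")
    attr_orth = orthogonalize(attr, masc)
    masc_orth = orthogonalize(masc, attr)
    attr_orth.save(run_dir / "direction_attr_orth.json")
    masc_orth.save(run_dir / "direction_masc_orth.json")
    _write_manifest(run_dir, "orthogonalize", {})
    return {"attr_orth": attr_orth, "masc_orth": masc_orth}


def stage_transform(
    run_dir: str | Path,
    faces_file: str,
    direction_file: str,
    out_file: str,
    levels: tuple[float, ...] = (-3, -2, -1, 0, 1, 2, 3),
) -> None:
    """Exaggerate the faces of one file along one stored direction."""
    run_dir = Path(run_dir)
    faces = read_faces(run_dir / faces_file)
    direction = TraitDirection.load(run_dir / direction_file)
    name = Path(direction_file).stem.replace("direction_", "")
    out = transform_faces(faces, direction, TransformSpec(name, tuple(levels)))
    write_faces(out, run_dir / out_file)
    _write_manifest(
        run_dir,
        f"transform_{name}",
        {"faces": faces_file, "direction": direction_file, "levels": list(levels)},
    )


def stage_simulate_exp2(
    run_dir: str | Path, seed: int = 100, n_base_faces: int = 20, n_raters: int = 16
) -> pd.DataFrame:
    """Generate the four validation rating cells on orthogonalized directions."""
    run_dir = Path(run_dir)
    truth = _truth_from_json(run_dir / "truth.json")
    attr_orth = TraitDirection.load(run_dir / "direction_attr_orth.json")
    masc_orth = TraitDirection.load(run_dir / "direction_masc_orth.json")
    config = SimConfig.for_scenario(
        "exp2_attr_orth", seed=seed, n_faces=n_base_faces, n_raters=n_raters
    )
    trials, stimuli = simulate_experiment2(truth, attr_orth, masc_orth, config)
    write_faces(stimuli, run_dir / "stimuli_exp2.csv")
    for task, tr in EXP2_CELLS:
        cell = trials[(trials["task"] == task) & (trials["transform"] == tr)]
        write_ratings(cell, run_dir / f"trials_{task}_{tr}.csv")
    _write_manifest(
        run_dir,
        "simulate_exp2",
        {"seed": seed, "n_base_faces": n_base_faces, "n_raters": n_raters},
    )
    return trials


def _write_fit(fit: PosteriorSummary, outdir: Path, meta: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fit.table.reset_index().to_csv(outdir / "posterior_summary.csv", index=False)
    fixed = {k: v for k, v in fit.draws.items() if k.startswith("b_")}
    chains = next(iter(fixed.values())).shape[0]
    frame = pd.DataFrame(
        {"chain": np.repeat(np.arange(chains), next(iter(fixed.values())).shape[1])}
    )
    for k, v in fixed.items():
        frame[k] = v.reshape(-1)
    frame.to_csv(outdir / "fixed_draws.csv", index=False)
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


def stage_validate(
    run_dir: str | Path,
    trials_file: str,
    out_subdir: str,
    mcmc: MCMCConfig | None = None,
    model_selection: bool = False,
) -> PosteriorSummary:
    """Fit the hierarchical regression to one trial file.

    With ``model_selection`` the full candidate lattice is ranked by WAIC
    and the best model's posterior is written; otherwise the full model
    (linear + quadratic + both sex factors) is fitted directly.
    """
    run_dir = Path(run_dir)
    mcmc = mcmc if mcmc is not None else MCMCConfig()
    trials = read_ratings(run_dir / trials_file)
    outdir = run_dir / out_subdir
    if model_selection:
        comparison = select_best(trials, candidate_specs(), mcmc)
        comparison.ladder.to_csv(run_dir / f"{out_subdir}_waic_ladder.csv", index=False)
        fit = comparison.best_fit
        best = comparison.best
    else:
        fit = fit_hierarchical(trials, ModelSpec(), mcmc)
        best = fit.spec.name
        w, _, p_eff = waic_detail(fit)
        pd.DataFrame([{"model": best, "waic": w, "p_waic": p_eff}]).to_csv(
            run_dir / f"{out_subdir}_waic_ladder.csv", index=False
        )
    task = trials["task"].iloc[0]
    meta = {
        "trials_file": trials_file,
        "task": task,
        "model": best,
        "mcmc": asdict(mcmc),
        "max_rhat": fit.max_rhat(),
    }
    _write_fit(fit, outdir, meta)
    _write_manifest(
        run_dir,
        f"validate_{out_subdir}",
        {"trials": trials_file, "mcmc": asdict(mcmc), "model_selection": model_selection},
    )
    return fit


def _load_draws(outdir: Path) -> dict[str, np.ndarray]:
    frame = pd.read_csv(outdir / "fixed_draws.csv")
    chains = frame["chain"].nunique()
    out = {}
    for col in frame.columns:
        if col == "chain":
            continue
        out[col] = frame[col].to_numpy().reshape(chains, -1)
    return out


def stage_compare(run_dir: str | Path, terms: tuple[str, ...] = ("b_level", "b_level2")) -> pd.DataFrame:
    """Generated-quantity contrasts between the two transformations.

    For each rating task, subtract the exaggeration coefficients of the
    nuisance-transformation fit from those of the target-transformation
    fit, draw by draw.
    """
    run_dir = Path(run_dir)
    fits = {}
    for task, tr in EXP2_CELLS:
        outdir = run_dir / f"validate_{task}_{tr}"
        if not outdir.exists():
            raise FormatError(f"missing validation output {outdir}")
        fits[(task, tr)] = _load_draws(outdir)
    rows = []
    target_of = {"attractiveness": "attr_orth", "sexual_dimorphism": "masc_orth"}
    for task in TASKS:
        target, nuis = target_of[task], [t for t in TRANSFORMS if t != target_of[task]][0]
        for term in terms:
            a, b = fits[(task, target)].get(term), fits[(task, nuis)].get(term)
            if a is None or b is None:
                continue
            kept = min(a.shape[1], b.shape[1])
            delta = (a[:, :kept] - b[:, :kept]).reshape(-1)
            lo, hi = np.percentile(delta, [2.5, 97.5])
            rows.append(
                {
                    "task": task,
                    "hypothesis": f"{target} - {nuis}",
                    "term": term,
                    "eap": delta.mean(),
                    "cri_low": lo,
                    "cri_high": hi,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "compare_table.csv", index=False, float_format="%.4f")
    _write_manifest(run_dir, "compare", {"terms": list(terms)})
    return table


def stage_report(run_dir: str | Path) -> str:
    """Human-readable dissociation summary over the four validation fits.

    PASS requires, for both transformations, that the target task's linear
    exaggeration coefficient has a 95% CrI excluding 0 while the nuisance
    task's contains 0.
    """
    run_dir = Path(run_dir)
    lines = ["Dissociation check (linear exaggeration term, 95% CrI)", ""]
    target_task = {"attr_orth": "attractiveness", "masc_orth": "sexual_dimorphism"}
    ok = True
    for tr in TRANSFORMS:
        for task in TASKS:
            outdir = run_dir / f"validate_{task}_{tr}"
            summary = pd.read_csv(outdir / "posterior_summary.csv").set_index("parameter")
            row = summary.loc["b_level"]
            lo, hi = row["cri_low"], row["cri_high"]
            is_target = task == target_task[tr]
            if is_target:
                good = not (lo <= 0.0 <= hi)
                expect = "CrI excludes 0"
            else:
                good = lo <= 0.0 <= hi
                expect = "CrI contains 0"
            ok &= good
            lines.append(
                f"  {tr:9s} {task:18s} b_level={row['eap']:+.3f} "
                f"[{lo:+.3f}, {hi:+.3f}]  {expect}: {'ok' if good else 'VIOLATED'}"
            )
        lines.append("")
    lines.append(f"dissociation: {'PASS' if ok else 'FAIL'}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    _write_manifest(run_dir, "report", {})
    return text


def run_default_pipeline(
    run_dir: str | Path,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    n_faces: int = 400,
    n_raters_exp1: int = 20,
    n_base_faces: int = 20,
    n_raters_exp2: int = 16,
    cos_angle: float = -0.4,
    model_selection: bool = False,
) -> str:
    """simulate -> build -> orthogonalize -> transform -> validate -> compare -> report."""
    run_dir = Path(run_dir)
    stage_simulate(run_dir, seed=seed, cos_angle=cos_angle, n_faces=n_faces,
                   n_raters=n_raters_exp1)
    for task in TASKS:
        stage_build(run_dir, task)
    stage_orthogonalize(run_dir)
    stage_simulate_exp2(run_dir, seed=seed + 10, n_base_faces=n_base_faces,
                        n_raters=n_raters_exp2)
    for task, tr in EXP2_CELLS:
        stage_validate(
            run_dir,
            f"trials_{task}_{tr}.csv",
            f"validate_{task}_{tr}",
            mcmc=mcmc,
            model_selection=model_selection,
        )
    stage_compare(run_dir)
    return stage_report(run_dir)
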