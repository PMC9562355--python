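"""End-to-end orchestration: simulate -> prepare -> fit -> classify ->
trait space -> scenarios -> report.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be re-run individually from the CLI.  A run
manifest records the resolved-configuration hash, seeds, per-stage timings,
software versions and output paths; stage outputs are reused on resume only
while the configuration hash matches, so any config change invalidates the
cache.  The pipeline is a pure function of (config, seed): re-running with
identical settings reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import associated_sets, classify_fit
from .config import config_hash, load_config
from .data_io import (
    filter_species,
    read_detections,
    read_site_covariates,
    read_traits,
    select_corals,
    write_detections,
    write_site_covariates,
)
from .occupancy import ModelConfig, assemblage_mean, fit as fit_model
from .scenarios import (
    compare_scenarios,
    per_coral_loss,
    random_loss,
    total_loss,
    vertex_weighted_loss,
)
from .synthetic import (
    CommunityHyperparams,
    CoverConfig,
    default_occasions,
    simulate_covariates,
    simulate_detection_history,
    simulate_species_params,
    simulate_traits,
)
from .traitspace import TraitSpace, build_trait_space

__all__ = ["run_pipeline", "summarize_run", "RunManifest", "PipelineError", "STAGES"]

STAGES = ("simulate", "prepare", "fit", "classify", "traitspace", "scenarios", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, completed: list[str]):
        super().__init__(f"stage {stage!r} failed: {cause} (completed: {completed})")
        self.stage = stage
        self.completed = completed


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {seconds, outputs}
    input_digests: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: list[str]) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3), "outputs": outputs}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(**d)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(base: int, k: int) -> int:
    return (int(base) * 1000 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, out: Path) -> list[str]:
    sim = cfg["simulate"]
    seed = cfg["seed"]
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)

    coral_taxa = tuple(f"coral{c:02d}" for c in range(sim["n_corals"]))
    cov = simulate_covariates(
        sim["n_sites"],
        CoverConfig(**sim["cover"]),
        seed=_stage_seed(seed, 1),
        coral_taxa=coral_taxa,
    )
    hyper = CommunityHyperparams(**sim["community"])
    occ = default_occasions(
        sim["n_sites"], seed=_stage_seed(seed, 2), **sim["occasions"]
    )

    adults = simulate_species_params(sim["n_species"], hyper, seed=_stage_seed(seed, 3))
    rng = np.random.default_rng(_stage_seed(seed, 4))
    juv_ix = np.sort(
        rng.choice(sim["n_species"], size=sim["n_juvenile_species"], replace=False)
    )
    juveniles = simulate_species_params(
        len(juv_ix),
        hyper,
        seed=_stage_seed(seed, 5),
        species_id=[adults.species_id[i] for i in juv_ix],
        body_length=adults.body_length[juv_ix],
    )

    outputs = []
    truth_frames = []
    for stage, params, s in (
        ("adult", adults, 6),
        ("juvenile", juveniles, 7),
    ):
        if params.n_species == 0:
            continue
        dh, truth = simulate_detection_history(
            params, cov, occ, hyper, seed=_stage_seed(seed, s), stage=stage
        )
        path = d / f"detections_{stage}.csv"
        write_detections(dh, path)
        outputs.append(str(path))
        truth_frames.append(
            pd.DataFrame(
                {
                    "species_id": params.species_id,
                    "stage": stage,
                    "alpha": params.alpha,
                    "beta1": params.beta1,
                    "beta2": params.beta2,
                    "p_intercept": params.p_intercept,
                    "body_length": params.body_length,
                }
            )
        )

    write_site_covariates(cov, d / "site_covariates_raw.csv")
    traits = simulate_traits(
        sim["n_species"],
        seed=_stage_seed(seed, 8),
        species_id=adults.species_id,
        body_length=adults.body_length,
    )
    traits.to_csv(d / "traits.csv")
    pd.concat(truth_frames, ignore_index=True).to_csv(d / "truth.csv", index=False)
    meta = {"seed": seed, "config": cfg["simulate"]}
    (d / "simulate_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    outputs += [
        str(d / "site_covariates_raw.csv"),
        str(d / "traits.csv"),
        str(d / "truth.csv"),
    ]
    return outputs


def _stage_prepare(cfg: dict, out: Path) -> list[str]:
    d = out / "prepare"
    d.mkdir(parents=True, exist_ok=True)
    cov = read_site_covariates(out / "simulate" / "site_covariates_raw.csv")
    corals = select_corals(cov, min_sites=cfg["prepare"]["min_sites"])
    write_site_covariates(cov, d / "site_covariates.csv")

    info: dict = {"selected_corals": corals, "min_sites": cfg["prepare"]["min_sites"]}
    outputs = [str(d / "site_covariates.csv")]
    for stage in cfg["fit"]["stages"]:
        src = out / "simulate" / f"detections_{stage}.csv"
        if not src.exists():
            continue
        dh = read_detections(src)
        dh, report = filter_species(dh, cfg["prepare"]["unresolved_species"])
        path = d / f"detections_{stage}.csv"
        write_detections(dh, path)
        outputs.append(str(path))
        info[f"filter_{stage}"] = {
            "n_input": report.n_input,
            "n_kept": report.n_kept,
            "n_dropped_zero": len(report.dropped_zero_detections),
            "n_dropped_unresolved": len(report.dropped_unresolved),
        }
    (d / "prepare.json").write_text(json.dumps(info, indent=2))
    outputs.append(str(d / "prepare.json"))
    return outputs


def _stage_fit(cfg: dict, out: Path) -> list[str]:
    d = out / "fit"
    d.mkdir(parents=True, exist_ok=True)
    prep = json.loads((out / "prepare" / "prepare.json").read_text())
    selected = prep["selected_corals"]
    requested = cfg["fit"]["corals"]
    if requested is None:
        corals = selected
    else:
        bad = [c for c in requested if c not in selected]
        if bad:
            raise ValueError(
                f"corals {bad} do not satisfy the inclusion rule "
                f"(non-zero cover in >= {prep['min_sites']} sites)"
            )
        corals = list(requested)

    cov = read_site_covariates(out / "prepare" / "site_covariates.csv")
    fcfg = cfg["fit"]
    class_rows, diag_all, assemblage_rows, outputs = [], {}, [], []
    run_id = 0
    for stage in fcfg["stages"]:
        src = out / "prepare" / f"detections_{stage}.csv"
        if not src.exists():
            continue
        dh = read_detections(src)
        for coral in corals:
            mc = ModelConfig(
                coral_taxon=coral,
                life_stage=stage,
                n_chains=fcfg["n_chains"],
                n_saved_per_chain=fcfg["n_saved_per_chain"],
                warmup=fcfg["warmup"],
                ci_levels=tuple(fcfg["ci_levels"]),
                seed=_stage_seed(cfg["seed"], 100 + run_id),
                pooling=fcfg["pooling"],
                plot_effect=fcfg["plot_effect"],
                shared_detection=fcfg["shared_detection"],
                compute_bpv=fcfg["compute_bpv"],
                bpv_draws=fcfg["bpv_draws"],
            )
            ps, diag = fit_model(dh, cov, mc)
            run_id += 1
            cls = classify_fit(
                ps,
                ci_level=cfg["classify"]["ci_level"],
                turf_rule=cfg["classify"]["turf_rule"],
            )
            class_rows.append(cls)
            diag_all[f"{coral}/{stage}"] = diag.to_dict()
            for which in ("beta1", "beta2"):
                am = assemblage_mean(ps, which)
                assemblage_rows.append(
                    {
                        "coral_taxon": coral,
                        "stage": stage,
                        "coefficient": which,
                        "median": float(np.median(am)),
                        "mean": float(am.mean()),
                        "lo90": float(np.quantile(am, 0.05)),
                        "hi90": float(np.quantile(am, 0.95)),
                        "n_draws": int(am.size),
                    }
                )
            if fcfg["save_draws"]:
                path = d / f"draws_{coral}_{stage}.csv"
                ps.to_tidy().to_csv(path, index=False)
                outputs.append(str(path))

    pd.concat(class_rows, ignore_index=True).to_csv(
        d / "classifications.csv", index=False
    )
    pd.DataFrame(assemblage_rows).to_csv(d / "assemblage.csv", index=False)
    (d / "diagnostics.json").write_text(json.dumps(diag_all, indent=2))
    return outputs + [
        str(d / "classifications.csv"),
        str(d / "assemblage.csv"),
        str(d / "diagnostics.json"),
    ]


def _stage_classify(cfg: dict, out: Path) -> list[str]:
    d = out / "classify"
    d.mkdir(parents=True, exist_ok=True)
    cls = pd.read_csv(out / "fit" / "classifications.csv")
    sets = associated_sets(cls)
    union_rows = [
        {"stage": stage, "species_id": sp}
        for stage, spp in sorted(sets.union.items())
        for sp in sorted(spp)
    ]
    pd.DataFrame(union_rows, columns=["stage", "species_id"]).to_csv(
        d / "associated_union.csv", index=False
    )
    sets.counts.to_csv(d / "category_counts.csv", index=False)
    per_coral_rows = [
        {"stage": stage, "coral_taxon": coral, "species_id": sp}
        for stage, by_coral in sorted(sets.per_coral.items())
        for coral, spp in sorted(by_coral.items())
        for sp in sorted(spp)
    ]
    pd.DataFrame(
        per_coral_rows, columns=["stage", "coral_taxon", "species_id"]
    ).to_csv(d / "associated_per_coral.csv", index=False)
    return [
        str(d / "associated_union.csv"),
        str(d / "category_counts.csv"),
        str(d / "associated_per_coral.csv"),
    ]


def _stage_traitspace(cfg: dict, out: Path) -> list[str]:
    d = out / "traitspace"
    d.mkdir(parents=True, exist_ok=True)
    traits = read_traits(out / "simulate" / "traits.csv")
    ts = build_trait_space(
        traits,
        trait_set=cfg["traitspace"]["trait_set"],
        n_axes=cfg["traitspace"]["n_axes"],
        correction=cfg["traitspace"]["correction"],
    )
    ts.coordinates_df().to_csv(d / "coordinates.csv")
    pd.DataFrame({"eigenvalue": ts.eigenvalues}).to_csv(
        d / "eigenvalues.csv", index_label="axis"
    )
    pd.DataFrame({"species_id": ts.hull_vertex_ids}).to_csv(
        d / "hull_vertices.csv", index=False
    )
    (d / "space.json").write_text(
        json.dumps({"area_complete": ts.area_complete, "n_axes": ts.coordinates.shape[1]})
    )
    return [
        str(d / "coordinates.csv"),
        str(d / "eigenvalues.csv"),
        str(d / "hull_vertices.csv"),
        str(d / "space.json"),
    ]


def load_trait_space(out: Path) -> TraitSpace:
    """Rebuild the TraitSpace object from a run's traitspace outputs."""
    d = out / "traitspace"
    coords = pd.read_csv(d / "coordinates.csv", index_col="species_id")
    eig = pd.read_csv(d / "eigenvalues.csv")["eigenvalue"].to_numpy()
    verts = pd.read_csv(d / "hull_vertices.csv")["species_id"].astype(str).tolist()
    meta = json.loads((d / "space.json").read_text())
    return TraitSpace(
        species_id=[str(s) for s in coords.index],
        coordinates=coords.to_numpy(),
        eigenvalues=eig,
        hull_vertex_ids=verts,
        area_complete=meta["area_complete"],
    )


def _stage_scenarios(cfg: dict, out: Path) -> list[str]:
    d = out / "scenarios"
    d.mkdir(parents=True, exist_ok=True)
    space = load_trait_space(out)
    union = pd.read_csv(out / "classify" / "associated_union.csv")
    per_coral = pd.read_csv(out / "classify" / "associated_per_coral.csv")
    stages = sorted(pd.read_csv(out / "fit" / "classifications.csv")["stage"].unique())
    scfg = cfg["scenarios"]
    seed = _stage_seed(cfg["seed"], 9)

    results = []
    for s_ix, stage in enumerate(stages):
        assoc = set(union.loc[union["stage"] == stage, "species_id"].astype(str))
        assoc &= set(space.species_id)
        sets = {
            coral: set(grp["species_id"].astype(str)) & set(space.species_id)
            for coral, grp in per_coral[per_coral["stage"] == stage].groupby(
                "coral_taxon"
            )
        }
        results.append(total_loss(space, assoc, stage))
        results += per_coral_loss(space, sets, stage)
        sizes = sorted({len(assoc)} | {len(s) for s in sets.values()})
        for n_ix, n in enumerate(sizes):
            results.append(
                random_loss(
                    space, n, scfg["n_runs"],
                    seed=_stage_seed(seed, 2 * (100 * s_ix + n_ix)),
                    stage=stage,
                )
            )
            results.append(
                vertex_weighted_loss(
                    space, n, scfg["n_runs"],
                    vertex_weight=scfg["vertex_weight"],
                    seed=_stage_seed(seed, 2 * (100 * s_ix + n_ix) + 1),
                    refresh=scfg["refresh_vertices"],
                    stage=stage,
                )
            )

    long, comp = compare_scenarios(results)
    # size-matched comparisons only
    comp = comp[comp["det_n_removed"] == comp["random_n_removed"]].reset_index(
        drop=True
    )
    long.to_csv(d / "scenario_results.csv", index=False)
    comp.to_csv(d / "comparison.csv", index=False)
    comp.to_json(d / "comparison.json", orient="records", indent=2)
    return [
        str(d / "scenario_results.csv"),
        str(d / "comparison.csv"),
        str(d / "comparison.json"),
    ]


def summarize_run(out: Path | str) -> dict:
    """Dataset, classification and scenario summaries for a completed run."""
    out = Path(out)
    report: dict = {}

    cov = read_site_covariates(out / "prepare" / "site_covariates.csv")
    cover_summary = {
        taxon: {
            "mean": float(cov.covers[taxon].mean()),
            "min": float(cov.covers[taxon].min()),
            "max": float(cov.covers[taxon].max()),
            "n_sites_present": int((cov.covers[taxon] > 0).sum()),
        }
        for taxon in cov.covers.columns
    }
    report["covers"] = cover_summary
    report["n_sites"] = len(cov.sites)

    occasions = 0
    det_stats = {}
    for stage in ("adult", "juvenile"):
        path = out / "prepare" / f"detections_{stage}.csv"
        if not path.exists():
            continue
        dh = read_detections(path)
        if stage == "adult":
            occasions = int(dh.n_occasions.sum())
        per_sp = dh.detections_per_species()
        det_stats[stage] = {
            "n_species": dh.n_species,
            "detections_mean": float(per_sp.mean()),
            "detections_sd": float(per_sp.std(ddof=1)),
        }
    report["n_occasions"] = occasions
    report["detections"] = det_stats

    counts_path = out / "classify" / "category_counts.csv"
    if counts_path.exists():
        report["category_counts"] = pd.read_csv(counts_path).to_dict("records")
        union = pd.read_csv(out / "classify" / "associated_union.csv")
        report["n_coral_associated"] = {
            stage: int((union["stage"] == stage).sum())
            for stage in union["stage"].unique()
        }
    diag_path = out / "fit" / "diagnostics.json"
    if diag_path.exists():
        diags = json.loads(diag_path.read_text())
        report["fits"] = {
            run: {"max_rhat": v["max_rhat"], "bpv": v["bpv"], "converged": v["converged"]}
            for run, v in diags.items()
        }
    comp_path = out / "scenarios" / "comparison.csv"
    if comp_path.exists():
        report["scenario_comparison"] = pd.read_csv(comp_path).to_dict("records")
    return report


def _stage_report(cfg: dict, out: Path) -> list[str]:
    report = summarize_run(out)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, default=str))
    return [str(path)]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "prepare": _stage_prepare,
    "fit": _stage_fit,
    "classify": _stage_classify,
    "traitspace": _stage_traitspace,
    "scenarios": _stage_scenarios,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_pipeline(
    cfg: dict | str | Path | None = None,
    outdir: str | Path = "runs/default",
    stages: list[str] | None = None,
    resume: bool = False,
) -> RunManifest:
    """Execute the pipeline stages in order, writing a run manifest.

    ``cfg`` may be a resolved config dict, a YAML path, or None (defaults).
    With ``resume=True``, stages whose outputs exist under an identical
    config hash are skipped.  Any stage failure raises
    :class:`PipelineError` naming the stage and listing completed stages.
    """
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)

    manifest_path = out / "manifest.json"
    manifest = None
    if resume and manifest_path.exists():
        old = RunManifest.load(manifest_path)
        if old.config_hash == chash:
            manifest = old
    if manifest is None:
        manifest = RunManifest(
            config_hash=chash,
            seed=cfg["seed"],
            versions={
                "coralfish": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        )
    (out / "config_resolved.json").write_text(
        json.dumps(cfg, indent=2, default=str)
    )

    todo = list(stages or STAGES)
    unknown = [s for s in todo if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")

    completed = [s for s in STAGES if s in manifest.stages]
    for stage in STAGES:
        if stage not in todo:
            continue
        if resume and stage in manifest.stages and all(
            Path(p).exists() for p in manifest.stages[stage]["outputs"]
        ):
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FN[stage](cfg, out)
        except Exception as exc:  # halt with the stage named
            manifest.save(manifest_path)
            raise PipelineError(stage, exc, completed) from exc
        manifest.record(stage, time.perf_counter() - t0, outputs)
        for p in outputs:
            manifest.input_digests[p] = _digest(Path(p))
        completed.append(stage)
        manifest.save(manifest_path)
    return manifest
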