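"""End-to-end orchestration: simulate (optional) -> ancestry -> geographic
clines -> genomic clines -> diversity, with a reproducibility manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import ParentalReference, estimate_ancestry
from .diversity import basic_stats, fst, fst_linearized, mantel, transect_profile
from .genomclines import run_genomic_clines
from .geoclines import compound_allele_reduction, fit_all_clines
from .io import read_meta_csv, read_structure_file, write_structure_file
from .simulate import SimulationConfig, make_fixture_dataset

log = logging.getLogger("hybridcline")


class PipelineError(RuntimeError):
    pass


def _load_config(config):
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _check_ids(gm, meta, what):
    known = set(meta["population"])
    offenders = sorted({p for p in gm.pops if p not in known})
    if offenders:
        raise PipelineError(
            f"{what}: population codes missing from metadata: {offenders}")


def run_pipeline(config, out_dir) -> Path:
    """Run the full analysis described by ``config`` into ``out_dir``.

    ``config`` (dict or YAML path) selects the input: either
    ``synthetic: {seed: ...}`` to generate the 13-population fixture dataset,
    or ``files: {ssr: ..., snp: ..., meta: ...}``.  ``ref_pops`` designates
    the parental reference populations (``white:``/``engelmann:`` lists).
    Writes per-stage TSVs plus ``manifest.json``; any stage failure aborts
    with the stage name.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stage = "load"
    manifest = {"version": __version__, "seed": seed, "config": cfg,
                "stages": []}
    try:
        if "synthetic" in cfg:
            gm_ssr, gm_snp, meta = make_fixture_dataset(
                seed=int(cfg["synthetic"].get("seed", seed)))
        else:
            files = cfg["files"]
            gm_ssr = read_structure_file(files["ssr"], files.get("dialect", "two-row"),
                                         marker_class="SSR")
            gm_snp = read_structure_file(files["snp"], files.get("dialect", "two-row"),
                                         marker_class="SNP")
            meta = read_meta_csv(files["meta"])
        _check_ids(gm_ssr, meta, "SSR genotypes")
        _check_ids(gm_snp, meta, "SNP genotypes")
        manifest["stages"].append(stage)

        ref_cfg = cfg.get("ref_pops", {"white": ["FN"],
                                       "engelmann": ["E1", "E2", "E3"]})
        pops_w, pops_e = list(ref_cfg["white"]), list(ref_cfg["engelmann"])

        stage = "ancestry"
        ref_snp = ParentalReference.from_panels(gm_snp, pops_w, pops_e)
        anc = estimate_ancestry(gm_snp, ref_snp)
        anc.to_csv(out / "ancestry.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "geoclines"
        ref_ssr = ParentalReference.from_panels(gm_ssr, pops_w, pops_e)
        reduced, mapping = compound_allele_reduction(gm_ssr, ref_ssr)
        mapping.to_csv(out / "ssr_compound_mapping.tsv", sep="\t", index=False)
        ssr_clines = fit_all_clines(reduced, meta)
        ssr_clines.to_csv(out / "ssr_clines.tsv", sep="\t", index=False)
        snp_clines = fit_all_clines(gm_snp, meta)
        snp_clines.to_csv(out / "snp_clines.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "genomclines"
        gc_cfg = cfg.get("genomic_clines", {})
        table, _ = run_genomic_clines(
            gm_snp, anc["h"].to_numpy(), ref_snp,
            B=int(gc_cfg.get("permutations", 1000)),
            alpha=float(gc_cfg.get("alpha", 1e-4)),
            seed=seed, pops_w=pops_w, pops_e=pops_e)
        table.to_csv(out / "genomic_clines.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "diversity"
        div = basic_stats(gm_ssr)
        div.per_pop_locus.to_csv(out / "diversity_pop_locus.tsv", sep="\t",
                                 index=False)
        div.per_pop.to_csv(out / "diversity_pop.tsv", sep="\t", index=False)
        theta, pairwise = fst(gm_ssr)
        pairwise.to_csv(out / "fst_pairwise.tsv", sep="\t")
        pops = list(pairwise.index)
        dist_km = meta.set_index("population").loc[pops, "distance_km"].to_numpy()
        d_geo = np.abs(dist_km[:, None] - dist_km[None, :])
        r, p = mantel(fst_linearized(pairwise.to_numpy()), d_geo,
                      n_perm=int(cfg.get("mantel_permutations", 1000)),
                      seed=seed)
        center = float(np.nanmean(
            snp_clines.loc[~snp_clines["no_cline"], "center"]))
        profile, offsets = transect_profile(div, meta, center)
        profile.to_csv(out / "transect_profile.tsv", sep="\t", index=False)
        with open(out / "diversity_summary.json", "w") as fh:
            json.dump({"fst_global": theta, "mantel_r": r, "mantel_p": p,
                       "mean_snp_cline_center_km": center,
                       "peak_offsets_km": offsets}, fh, indent=2)
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def simulate_to_files(config, out_dir) -> Path:
    """Run the forward simulator and export snapshots + per-individual TSV."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(cfg.get("simulate", cfg))
    for key in ("trait_optima", "allelic_effects", "snapshot_generations"):
        if key in sim_kwargs and isinstance(sim_kwargs[key], list):
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sc = SimulationConfig(**sim_kwargs)
    from .simulate import run as sim_run
    result = sim_run(sc)
    for gen, gm in result.snapshots:
        write_structure_file(gm, out / f"snapshot_gen{gen}.str")
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    st = result.final_state
    pd.DataFrame({"id": [f"i{i}" for i in range(st.n_individuals)],
                  "deme": st.deme + 1, "G": st.G, "P": st.P, "W": st.W}
                 ).to_csv(out / "individuals_final.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"version": __version__, "config": sim_kwargs}, fh,
                  indent=2, default=str)
    return out
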