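"""End-to-end run: simulate -> IBD -> selection scan -> ancestry -> load.

Stages are chained on a single simulated scenario (or user-supplied files),
every stage's tables are written to the output directory, and one
structured JSON report collects the headline results together with the
exact configuration used. The report contains no timestamps, so an
identical config + seed reproduces it byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ancestry as anc
from . import ibd
from . import io as pio
from . import load as gl
from . import scan
from .core import ConfigurationError
from .sim import SimulationConfig, simulate, write_dataset

logger = logging.getLogger("polyped")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr for h in logger.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setLevel(logging.WARNING)
        logger.addHandler(sh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: pio.RunConfig) -> dict:
    """Execute all stages in order and return the structured report.

    Any stage failure aborts with a :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
    }

    # ---- inputs ------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulation is not None:
            sim_cfg = SimulationConfig.from_dict(
                {**config.simulation, "seed": config.simulation.get("seed", config.seed)}
            )
            dataset = simulate(sim_cfg)
            write_dataset(dataset, out_dir / "data")
            matrix = dataset.genotypes
            donor_panel = dataset.donor_panel
            assemblies = dataset.assemblies
            genes, qtl = dataset.genes, dataset.qtl
            classification = gl.classify_sites(dataset.truth.site_classes)
            pedigree = sim_cfg.pedigree
        else:
            for name, val in (("vcf", config.vcf), ("groups_file", config.groups_file)):
                if val is None:
                    raise ConfigurationError(f"config requires {name} when no simulation is set")
            groups = pio.read_groups(config.groups_file)
            matrix = pio.read_vcf(config.vcf, groups=groups)
            donor_panel = None
            assemblies = {
                name: __import__("polyped.core", fromlist=["AssemblySet"]).AssemblySet.from_fasta(p, name)
                for name, p in config.assemblies.items()
            }
            genes = pio.read_bed(config.genes_bed) if config.genes_bed else pd.DataFrame(columns=pio.BED_COLUMNS)
            qtl = pio.read_bed(config.qtl_bed) if config.qtl_bed else pd.DataFrame(columns=pio.BED_COLUMNS)
            classification = (
                gl.classify_sites(pio.read_classification(config.classification))
                if config.classification
                else None
            )
            pedigree = None
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- IBD tracing -------------------------------------------------
    stage = "ibd"
    try:
        ibd_section = {}
        if config.ibd_child in assemblies:
            parents = {
                n: a
                for n, a in assemblies.items()
                if n not in (config.ibd_child, "ancestral")
            }
            table, track = ibd.trace_origin(
                assemblies[config.ibd_child],
                parents,
                block_size=config.block_size,
                anchor_k=config.anchor_k,
                min_match_fraction=config.min_match_fraction,
            )
            if config.ibd_decompose in set(track["origin"]) and pedigree is not None:
                gp_names = next(
                    ((p1, p2) for c, p1, p2 in pedigree.edges if c == config.ibd_decompose),
                    None,
                )
                if gp_names:
                    track = ibd.decompose_parent(
                        track,
                        config.ibd_decompose,
                        assemblies[config.ibd_child],
                        {n: assemblies[n] for n in set(gp_names)},
                        anchor_k=config.anchor_k,
                        min_match_fraction=config.min_match_fraction,
                    )
            summary = ibd.summarize_contributions(track)
            pio.write_bed(track.rename(columns={"origin": "id"}), out_dir / "ibd_track.bed")
            summary.to_csv(out_dir / "ibd_contributions.tsv", sep="\t", index=False)
            ibd_section = {
                "child": config.ibd_child,
                "contributions_percent": dict(
                    zip(summary["origin"], summary["percent"])
                ),
            }
        report["ibd"] = ibd_section
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- selection scan ----------------------------------------------
    stage = "scan"
    try:
        filtered = pio.filter_sites(matrix, maf=config.maf, max_missing=config.max_missing)
        pis = {
            g: scan.windowed_pi(filtered, g, config.window, config.step)
            for g in (config.scan_group_a, config.scan_group_b)
        }
        fst = scan.windowed_fst(
            filtered, config.scan_group_a, config.scan_group_b, config.window, config.step
        )
        if config.z_scope == "subgenome":
            z = np.full(len(fst), np.nan)
            subg = fst["chrom"].str.slice(0, 1)
            for s in subg.unique():
                m = (subg == s).to_numpy()
                z[m] = scan.zscore(fst["value"].to_numpy()[m])
            fst["z"] = z
        else:
            fst["z"] = scan.zscore(fst["value"].to_numpy())
        regions = scan.call_divergent_regions(fst, threshold=config.z_threshold)
        features = pd.concat([genes, qtl], ignore_index=True) if len(qtl) else genes
        annotated, n_features = scan.intersect_features(regions.regions, features)
        fst.to_csv(out_dir / "fst_windows.tsv", sep="\t", index=False)
        for g, df in pis.items():
            df.to_csv(out_dir / f"pi_windows_{g}.tsv", sep="\t", index=False)
        pio.write_bed(
            annotated.assign(id=lambda d: "region_" + d.index.astype(str))[
                ["chrom", "start", "end", "id"]
            ],
            out_dir / "divergent_regions.bed",
        )
        report["scan"] = {
            "groups": [config.scan_group_a, config.scan_group_b],
            "n_windows": int(len(fst)),
            "n_flagged_windows": regions.n_flagged_windows,
            "n_regions": int(len(regions.regions)),
            "divergent_bp": regions.total_bp,
            "n_overlapping_features": n_features,
            "mean_pi": {
                g: float(np.nanmean(df["value"])) for g, df in pis.items()
            },
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- local ancestry ----------------------------------------------
    stage = "ancestry"
    try:
        anc_section = {}
        if donor_panel is not None:
            query = matrix.subset_samples(
                [s for s in matrix.samples if matrix.groups[s] == config.ancestry_group]
            )
            panel_b = matrix.subset_samples(
                [s for s in matrix.samples if matrix.groups[s] == config.scan_group_b]
            )
            tracks, grid = anc.paint_population(
                query,
                donor_panel,
                panel_b,
                window_snps=config.window_snps,
                label_a="donor",
                label_b="background",
            )
            fixation = anc.population_ancestry_frequency(
                tracks, "donor", level=config.fixation_level
            )
            fixed = anc.call_fixed_introgressions(fixation, config.fixation_threshold)
            tracks.to_csv(out_dir / "ancestry_tracks.tsv", sep="\t", index=False)
            fixation.to_csv(out_dir / "ancestry_fixation.tsv", sep="\t", index=False)
            pio.write_bed(
                fixed.regions.assign(id="fixed_introgression")[
                    ["chrom", "start", "end", "id"]
                ],
                out_dir / "fixed_introgressions.bed",
            )
            anc_section = {
                "query_group": config.ancestry_group,
                "n_fixed_regions": int(len(fixed.regions)),
                "fixed_bp": fixed.total_bp,
                "unresolved_fraction": float(
                    (tracks["label"] == anc.UNRESOLVED).mean()
                ),
            }
        report["ancestry"] = anc_section
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- genetic load ------------------------------------------------
    stage = "load"
    try:
        load_section = {}
        if classification is not None:
            spectra = {}
            for g in pd.unique(matrix.groups.reindex(matrix.samples)):
                spec = gl.frequency_spectrum(matrix, classification, g, bins=config.bins)
                rel = gl.relative_load(spec)
                spectra[g] = {
                    "fixed_bin_deleterious": int(
                        spec.counts[gl.DELETERIOUS][spec.fixed_bin_index()]
                    ),
                    "fixed_bin_relative_load": _jsonable(rel[spec.fixed_bin_index()]),
                    "mean_deleterious_freq": _mean_class_freq(matrix, classification, g, gl.DELETERIOUS),
                    "mean_neutral_freq": _mean_class_freq(matrix, classification, g, gl.NEUTRAL),
                }
                spec.to_frame().to_csv(
                    out_dir / f"spectrum_{g}.tsv", sep="\t", index=False
                )
            table = gl.group_load_table(matrix, classification)
            table.to_csv(out_dir / "individual_load.tsv", sep="\t", index=False)
            load_section = {"groups": spectra}
        report["load"] = load_section
    except Exception as exc:
        raise StageError(stage, exc) from exc

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", report_path)
    return report


def _mean_class_freq(matrix, classification, group, site_class) -> float | None:
    cls = gl._aligned_classes(matrix, classification)
    freq, total = gl.group_frequencies(matrix, group)
    f = freq[(cls == site_class) & (total > 0)]
    f = f[np.isfinite(f) & (f > 0)]
    return float(f.mean()) if f.size else None
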