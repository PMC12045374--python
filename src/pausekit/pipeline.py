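"""End-to-end orchestration: one config in, a reproducible result bundle out.

Stage order: replicate consensus per assay -> cross-assay intersection ->
peak annotation -> pausing windows -> densities -> PRR -> classification ->
ECDF / K-S report -> metaplots -> ORA. Every output TSV gets a JSON
provenance sidecar (inputs, parameters, seed) and a run manifest records
SHA-256 digests of all outputs, so a rerun from the same config and inputs
can be verified byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import PausekitError, ValidationError
from . import genome_io, pausing, peaks as peaks_mod, metaplot as metaplot_mod
from . import enrichment

logger = logging.getLogger(__name__)

PAUSING_DEFAULTS: dict[str, Any] = {
    "promoter_up": 50,
    "promoter_down": 300,
    "body_gap": 300,
    "body_extent": "to-tes",
    "pseudocount": 0.1,
    "log2_threshold": 0.585,
    "min_activity_quantile": 0.25,
}
PEAKS_DEFAULTS: dict[str, Any] = {
    "fdr_max": 0.05,
    "min_sets": None,  # None = all replicates
    "overlap_rule": "any_bp",
    "reciprocal_fraction": 0.5,
    "intersect_extent": "strict",
    "promoter_window": 2000,
}
METAPLOT_DEFAULTS: dict[str, Any] = {
    "upstream": 100,
    "downstream": 2000,
    "bin": 10,
    "flank": 1000,
    "n_boot": 200,
}
ORA_DEFAULTS: dict[str, Any] = {"adjusted_p_max": 0.05}


@dataclass
class RunConfig:
    """Everything a run needs; serializable, so config + inputs reproduce it."""

    annotation: str
    coverage: dict[str, dict[str, str]]  # condition -> strand label -> path
    annotation_format: str = "gtf"
    peaks: dict[str, list[str]] = field(default_factory=dict)  # assay -> replicates
    peak_format: str = "narrowpeak"
    assay_coverage: dict[str, dict[str, str]] = field(default_factory=dict)
    gene_sets: str | None = None
    seed: int = 0
    make_plots: bool = False
    pausing: dict[str, Any] = field(default_factory=dict)
    peak_params: dict[str, Any] = field(default_factory=dict)
    metaplot: dict[str, Any] = field(default_factory=dict)
    ora: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pausing = {**PAUSING_DEFAULTS, **self.pausing}
        self.peak_params = {**PEAKS_DEFAULTS, **self.peak_params}
        self.metaplot = {**METAPLOT_DEFAULTS, **self.metaplot}
        self.ora = {**ORA_DEFAULTS, **self.ora}

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "annotation": self.annotation,
            "annotation_format": self.annotation_format,
            "coverage": copy.deepcopy(self.coverage),
            "peaks": copy.deepcopy(self.peaks),
            "peak_format": self.peak_format,
            "assay_coverage": copy.deepcopy(self.assay_coverage),
            "gene_sets": self.gene_sets,
            "seed": self.seed,
            "make_plots": self.make_plots,
            "pausing": dict(self.pausing),
            "peak_params": dict(self.peak_params),
            "metaplot": dict(self.metaplot),
            "ora": dict(self.ora),
        }


def validate_config(config: RunConfig) -> list[str]:
    """Collect every problem with a config; an empty list means valid."""
    problems: list[str] = []

    def check_file(path: str | None, what: str) -> None:
        if path is None:
            return
        if not os.path.isfile(path):
            problems.append(f"{what}: file not found: {path}")

    check_file(config.annotation, "annotation")
    if config.annotation_format not in ("gtf", "bed12"):
        problems.append(f"unknown annotation_format {config.annotation_format!r}")
    for cond in ("ctrl", "treat"):
        strands = config.coverage.get(cond)
        if not strands:
            problems.append(f"coverage: missing condition {cond!r}")
            continue
        keys = set(strands)
        if not (keys == {"+", "-"} or keys == {"."}):
            problems.append(
                f"coverage[{cond}]: strand keys must be {{'+','-'}} or {{'.'}}, "
                f"got {sorted(keys)}"
            )
        for strand, path in strands.items():
            check_file(path, f"coverage[{cond}][{strand}]")
    for assay, reps in config.peaks.items():
        if not reps:
            problems.append(f"peaks[{assay}]: no replicate files")
        for p in reps:
            check_file(p, f"peaks[{assay}]")
    for assay, conds in config.assay_coverage.items():
        for cond in ("ctrl", "treat"):
            if cond not in conds:
                problems.append(f"assay_coverage[{assay}]: missing {cond!r}")
            else:
                check_file(conds[cond], f"assay_coverage[{assay}][{cond}]")
    check_file(config.gene_sets, "gene_sets")

    pz = config.pausing
    for key in ("promoter_up", "promoter_down", "body_gap"):
        if pz[key] < 0:
            problems.append(f"pausing.{key} must be non-negative")
    if pz["pseudocount"] <= 0:
        problems.append("pausing.pseudocount must be positive")
    if pz["log2_threshold"] <= 0:
        problems.append("pausing.log2_threshold must be positive")
    if not (0.0 <= pz["min_activity_quantile"] < 1.0):
        problems.append("pausing.min_activity_quantile must be in [0, 1)")

    pk = config.peak_params
    if not (0.0 < pk["fdr_max"] <= 1.0):
        problems.append(f"peaks.fdr_max {pk['fdr_max']} outside (0, 1]")
    if pk["overlap_rule"] not in ("any_bp", "reciprocal_fraction"):
        problems.append(f"unknown peaks.overlap_rule {pk['overlap_rule']!r}")
    if pk["intersect_extent"] not in ("strict", "union"):
        problems.append(f"unknown peaks.intersect_extent {pk['intersect_extent']!r}")
    if pk["promoter_window"] <= 0:
        problems.append("peaks.promoter_window must be positive")

    mp = config.metaplot
    span = mp["upstream"] + mp["downstream"]
    if mp["bin"] <= 0:
        problems.append("metaplot.bin must be positive")
    elif span % mp["bin"] != 0:
        problems.append(
            f"metaplot window span {span} not divisible by bin {mp['bin']}"
        )
    if mp["bin"] > 0 and (2 * mp["flank"]) % mp["bin"] != 0:
        problems.append(
            f"metaplot centered span {2 * mp['flank']} not divisible by bin {mp['bin']}"
        )
    if not (0.0 < config.ora["adjusted_p_max"] <= 1.0):
        problems.append("ora.adjusted_p_max must be in (0, 1]")
    return problems


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(path: str, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    payload = {
        "stage": stage,
        "pausekit_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    if extra:
        payload["extra"] = extra
    with open(path + ".provenance.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: str, config: RunConfig, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    write_sidecar(path, config, stage)


def run_pausing_analysis(config: RunConfig, out_dir: str) -> dict[str, Any]:
    """Run every stage; returns a result dict with tables and output paths.

    Aborts with :class:`PausekitError` naming the failing stage. Outputs are
    deterministic: the same config and inputs give byte-identical files.
    """
    problems = validate_config(config)
    if problems:
        raise ValidationError("invalid config:\n  " + "\n  ".join(problems))
    os.makedirs(out_dir, exist_ok=True)
    results: dict[str, Any] = {"out_dir": out_dir}
    outputs: list[str] = []

    def emit(df: pd.DataFrame, name: str, stage: str) -> str:
        path = os.path.join(out_dir, name)
        _write_tsv(df, path, config, stage)
        outputs.append(path)
        return path

    current_stage = ["start"]

    def stage(name):
        current_stage[0] = name
        logger.info("stage: %s", name)

    try:
        stage("annotation")
        genes = genome_io.read_annotation(config.annotation, config.annotation_format)

        stage("consensus")
        pk = config.peak_params
        per_assay: dict[str, peaks_mod.ConsensusPeakSet] = {}
        for assay, rep_paths in sorted(config.peaks.items()):
            reps = [
                genome_io.read_peaks(p, format=config.peak_format)
                for p in rep_paths
            ]
            cps = peaks_mod.consensus(
                reps,
                min_sets=pk["min_sets"],
                fdr_max=pk["fdr_max"],
                overlap_rule=pk["overlap_rule"],
                reciprocal_fraction=pk["reciprocal_fraction"],
            )
            per_assay[assay] = cps
            path = os.path.join(out_dir, f"consensus_{assay}.narrowPeak")
            genome_io.write_peaks_narrowpeak(cps.peaks, path)
            write_sidecar(path, config, "consensus", {"assay": assay, "n_peaks": len(cps)})
            outputs.append(path)
        results["consensus_per_assay"] = per_assay

        stage("intersect")
        combined: peaks_mod.ConsensusPeakSet | None = None
        for assay in sorted(per_assay):
            combined = (
                per_assay[assay]
                if combined is None
                else peaks_mod.intersect_assays(
                    combined, per_assay[assay], extent=pk["intersect_extent"]
                )
            )
        if combined is not None:
            path = os.path.join(out_dir, "consensus_combined.narrowPeak")
            genome_io.write_peaks_narrowpeak(combined.peaks, path)
            write_sidecar(path, config, "intersect", {"n_peaks": len(combined)})
            outputs.append(path)
        results["consensus_combined"] = combined

        stage("annotate")
        if combined is not None and len(combined):
            annos = peaks_mod.annotate_peaks(
                combined, genes, promoter_window=pk["promoter_window"]
            )
            anno_df = pd.DataFrame(
                {
                    "chrom": [a.peak.interval.chrom for a in annos],
                    "start": [a.peak.interval.start for a in annos],
                    "end": [a.peak.interval.end for a in annos],
                    "fdr": [a.peak.fdr for a in annos],
                    "feature_class": [a.feature_class for a in annos],
                    "nearest_gene_id": [a.nearest_gene_id for a in annos],
                    "distance_to_tss": [a.distance_to_tss for a in annos],
                }
            )
            emit(anno_df, "peak_annotation.tsv", "annotate")
            results["peak_annotation"] = anno_df

        stage("windows")
        pz = config.pausing
        windows = pausing.build_windows(
            genes,
            promoter_up=pz["promoter_up"],
            promoter_down=pz["promoter_down"],
            body_gap=pz["body_gap"],
            body_extent=pz["body_extent"],
        )
        if not windows:
            raise ValidationError("no gene passed window construction")

        stage("densities/prr/classify")
        tracks: dict[str, dict[str, genome_io.CoverageTrack]] = {}
        for cond in ("ctrl", "treat"):
            tracks[cond] = {
                strand: genome_io.read_coverage(path, strand=strand)
                for strand, path in config.coverage[cond].items()
            }
        prr = pausing.prr_table(
            windows,
            tracks["ctrl"],
            tracks["treat"],
            pseudocount=pz["pseudocount"],
            log2_threshold=pz["log2_threshold"],
            min_activity_quantile=pz["min_activity_quantile"],
        )
        emit(prr, "prr.tsv", "prr")
        results["prr"] = prr
        group_counts = (
            prr["group"].value_counts().rename_axis("group").reset_index(name="n_genes")
        ).sort_values("group").reset_index(drop=True)
        emit(group_counts, "group_counts.tsv", "classify")
        results["group_counts"] = group_counts

        stage("ecdf/ks")
        classified = prr[prr["group"] != pausing.GROUP_EXCLUDED]
        ks_rows = []
        comparisons = [
            ("prr_treat_vs_ctrl_all", classified["prr_treat"], classified["prr_ctrl"]),
        ]
        for grp, label in (
            (pausing.GROUP_I, "groupI"),
            (pausing.GROUP_II, "groupII"),
        ):
            sub = prr[prr["group"] == grp]
            if len(sub):
                comparisons.append(
                    (f"prr_treat_vs_ctrl_{label}", sub["prr_treat"], sub["prr_ctrl"])
                )
                emit(
                    pausing.ecdf_table(sub["prr_treat"]),
                    f"ecdf_prr_treat_{label}.tsv",
                    "ecdf",
                )
                emit(
                    pausing.ecdf_table(sub["prr_ctrl"]),
                    f"ecdf_prr_ctrl_{label}.tsv",
                    "ecdf",
                )
        g1 = prr.loc[prr["group"] == pausing.GROUP_I, "log2_prr_fc"]
        g2 = prr.loc[prr["group"] == pausing.GROUP_II, "log2_prr_fc"]
        if len(g1) and len(g2):
            comparisons.append(("log2fc_groupI_vs_groupII", g1, g2))
        for name, a, b in comparisons:
            cmp_res = pausing.ks_two_sample(a, b)
            ks_rows.append(
                (name, len(a), len(b), cmp_res.ks_statistic, cmp_res.p_value)
            )
        ks_df = pd.DataFrame(
            ks_rows, columns=["comparison", "n_a", "n_b", "ks_statistic", "p_value"]
        )
        emit(ks_df, "ks_report.tsv", "ks")
        results["ks_report"] = ks_df

        stage("metaplots")
        mp = config.metaplot
        gene_by_id = {g.gene_id: g for g in genes}
        profiles: dict[str, pd.DataFrame] = {}
        for grp, label in ((pausing.GROUP_I, "groupI"), (pausing.GROUP_II, "groupII")):
            ids = prr.loc[prr["group"] == grp, "gene_id"]
            anchors = [
                (gene_by_id[i].chrom, gene_by_id[i].tss, gene_by_id[i].strand)
                for i in ids
                if i in gene_by_id
            ]
            if not anchors:
                continue
            for cond in ("ctrl", "treat"):
                mat = metaplot_mod.matrix_at_anchors(
                    tracks[cond],
                    anchors,
                    upstream=mp["upstream"],
                    downstream=mp["downstream"],
                    bin_size=mp["bin"],
                    row_ids=list(ids),
                )
                prof = metaplot_mod.profile(
                    mat, n_boot=mp["n_boot"], seed=config.seed
                )
                profiles[f"{label}_{cond}"] = prof
                emit(prof, f"metaprofile_tss_{label}_{cond}.tsv", "metaplot")
                mat_path = os.path.join(out_dir, f"metamatrix_tss_{label}_{cond}.tsv")
                mat.to_frame().to_csv(mat_path, sep="\t", float_format="%.6g")
                write_sidecar(mat_path, config, "metaplot")
                outputs.append(mat_path)
        results["profiles"] = profiles
        if combined is not None and len(combined):
            acc_track = None
            if config.assay_coverage:
                first = sorted(config.assay_coverage)[0]
                acc_track = genome_io.read_coverage(
                    config.assay_coverage[first]["ctrl"]
                )
            if acc_track is not None:
                cmat = metaplot_mod.centered_matrix(
                    acc_track, combined, flank=mp["flank"], bin_size=mp["bin"]
                )
                cprof = metaplot_mod.profile(cmat, n_boot=mp["n_boot"], seed=config.seed)
                emit(cprof, "metaprofile_peak_centered.tsv", "metaplot")
                results["peak_centered_profile"] = cprof
        if config.make_plots and profiles:
            plot_path = os.path.join(out_dir, "metaprofiles.png")
            metaplot_mod.plot_profile(profiles, plot_path)

        stage("fold_change_correlation")
        if combined is not None and len(combined) >= 3 and len(config.assay_coverage) >= 2:
            names = sorted(config.assay_coverage)[:2]
            pairs = []
            for name in names:
                pairs.append(
                    (
                        genome_io.read_coverage(config.assay_coverage[name]["ctrl"]),
                        genome_io.read_coverage(config.assay_coverage[name]["treat"]),
                    )
                )
            rho = peaks_mod.signal_fold_change_correlation(
                combined, pairs[0], pairs[1]
            )
            results["fold_change_spearman"] = rho
            corr_df = pd.DataFrame(
                {"assay_a": [names[0]], "assay_b": [names[1]],
                 "spearman_rho": [rho], "n_peaks": [len(combined)]}
            )
            emit(corr_df, "fold_change_correlation.tsv", "correlation")

        stage("ora")
        if config.gene_sets is not None:
            sets = enrichment.read_gmt(config.gene_sets)
            universe = set(classified["gene_id"])
            query = set(prr.loc[prr["group"] == pausing.GROUP_I, "gene_id"])
            if query and universe:
                ora = enrichment.hypergeom_ora(query, sets, universe)
                ora["significant"] = ora["adjusted_p"] < config.ora["adjusted_p_max"]
                emit(ora, "ora_groupI.tsv", "ora")
                results["ora"] = ora

        stage("manifest")
        manifest = {
            "pausekit_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": {
                os.path.basename(p): _sha256(p) for p in sorted(outputs)
            },
        }
        manifest_path = os.path.join(out_dir, "run_manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        results["manifest"] = manifest
        return results
    except PausekitError as exc:
        raise PausekitError(f"stage {current_stage[0]!r} failed: {exc}") from exc
    except Exception as exc:  # pragma: no cover - defensive
        raise PausekitError(f"stage {current_stage[0]!r} failed: {exc}") from exc
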