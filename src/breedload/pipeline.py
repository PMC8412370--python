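"""End-to-end orchestration: genotypes -> load statistics -> differentiation
-> candidate prioritization (-> association when a cohort is supplied).

Every run writes tabular reports plus a JSON run log carrying the package
version, the full parameter echo, the seed and sha256 checksums of every
input, so each emitted number is traceable to its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__, association, differentiation, io_model, load_stats

log = logging.getLogger("breedload")


@dataclass
class PipelineConfig:
    vcf: str
    outgroup_vcf: str
    breed_map: str
    annotations: str
    out_dir: str
    site_classes: tuple[str, ...] = ("synonymous", "nonsynonymous", "lof", "moderate", "high")
    convention: str = "methods"
    n_blocks: int = load_stats.DEFAULT_N_BLOCKS
    family_size: int | None = None
    statistics: tuple[str, ...] = ("R", "R2")
    fst_min: float = 0.7
    freq_min: float = 0.7
    phylop_min: float = 2.0
    focal_breed: str | None = None
    mask_bed: str | None = None
    cohort: str | None = None
    markers: tuple[str, ...] = ()
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("vcf", "outgroup_vcf", "breed_map", "annotations"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} input not found: {path}")
        if not 0 <= self.fst_min <= 1:
            raise ValueError("fst_min must be in [0, 1]")
        if not 0 <= self.freq_min <= 1:
            raise ValueError("freq_min must be in [0, 1]")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("site_classes", "statistics", "markers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("vcf", "outgroup_vcf", "breed_map", "annotations")
        },
        "stages": {},
        "outputs": {},
    }

    stage = "load genotypes"
    try:
        dataset = io_model.read_genotypes(config.vcf, config.breed_map)
        outgroup = io_model.read_outgroup(config.outgroup_vcf)
        dataset = io_model.polarize(dataset, outgroup)
        annotations = io_model.read_annotations(config.annotations)
        dataset = io_model.attach_annotations(dataset, annotations)
        classes = io_model.classify_sites(dataset.annotations, config.convention)
        class_masks = {
            c: classes[c].to_numpy() for c in config.site_classes if c in classes.columns
        }
        report["stages"][stage] = {
            "n_sites": dataset.n_sites,
            "breeds": dataset.breeds,
            "class_counts": {c: int(m.sum()) for c, m in class_masks.items()},
        }

        stage = "load statistics"
        mask = (
            load_stats.MaskSet.from_bed(config.mask_bed) if config.mask_bed else None
        )
        frames = []
        for statistic in config.statistics:
            tab = load_stats.all_pairs_load_table(
                dataset,
                class_masks,
                statistic=statistic,
                n_blocks=config.n_blocks,
                family_size=config.family_size,
            )
            frames.append(tab)
        load_table = pd.concat(frames, ignore_index=True)
        load_path = os.path.join(config.out_dir, "load.tsv")
        load_table.to_csv(load_path, sep="\t", index=False)
        report["outputs"]["load"] = load_path
        report["stages"][stage] = {"rows": len(load_table)}
        if mask is not None:
            masked_rows = []
            for statistic in ("R",):
                import itertools

                for a, b in itertools.combinations(dataset.breeds, 2):
                    for cls_name, cls_mask in class_masks.items():
                        comp = load_stats.masked_r_ab(
                            dataset, a, b, cls_mask, mask, n_blocks=config.n_blocks
                        )
                        masked_rows.append(
                            {
                                "breed_a": a,
                                "breed_b": b,
                                "site_class": cls_name,
                                "value": comp.value,
                                "se": comp.se,
                                "p": comp.p,
                                "n_sites": comp.n_sites,
                            }
                        )
            masked_path = os.path.join(config.out_dir, "load_masked.tsv")
            pd.DataFrame(masked_rows).to_csv(masked_path, sep="\t", index=False)
            report["outputs"]["load_masked"] = masked_path

        stage = "differentiation"
        pairwise = differentiation.pairwise_fst_table(dataset)
        fst_path = os.path.join(config.out_dir, "fst.tsv")
        pd.concat(
            [dataset.sites[["chrom", "pos", "ref", "alt"]], pairwise], axis=1
        ).to_csv(fst_path, sep="\t", index=False)
        report["outputs"]["fst"] = fst_path

        stage = "prioritization"
        focal = config.focal_breed or dataset.breeds[0]
        candidates = differentiation.stage1_candidates(
            dataset,
            pairwise,
            focal,
            fst_min=config.fst_min,
            freq_min=config.freq_min,
            phylop_min=config.phylop_min,
        )
        cand_path = os.path.join(config.out_dir, "candidates.tsv")
        differentiation.candidates_to_frame(candidates).to_csv(
            cand_path, sep="\t", index=False
        )
        report["outputs"]["candidates"] = cand_path
        report["stages"][stage] = {"focal_breed": focal, "n_candidates": len(candidates)}

        if config.cohort:
            stage = "association"
            cohort = association.read_cohort(config.cohort)
            markers = list(config.markers) or [
                c for c in cohort.columns if c not in association.COHORT_COLUMNS
            ]
            assoc_rows = []
            for marker in markers:
                geno = cohort[marker].dropna()
                if geno.nunique() < 2:
                    continue
                try:
                    uni = association.ols_fit(
                        cohort.rename(columns={marker: "genotype"}), "MMVD_status", ["genotype"]
                    )
                    inter = association.interaction_models(cohort, marker)
                except ValueError as err:  # e.g. single carrier -> collinear design
                    log.warning("skipping marker %s: %s", marker, err)
                    continue
                assoc_rows.append(
                    {
                        "marker": marker,
                        "beta_genotype": uni.coefficients.get("genotype"),
                        "p_genotype": uni.p_values.get("genotype"),
                        "beta_interaction": inter.coefficients.get("genotype:age"),
                        "p_interaction": inter.p_values.get("genotype:age"),
                        "model_r2": inter.r2,
                        "n": inter.n,
                    }
                )
            assoc_path = os.path.join(config.out_dir, "association.tsv")
            pd.DataFrame(assoc_rows).to_csv(assoc_path, sep="\t", index=False)
            report["outputs"]["association"] = assoc_path
            report["stages"][stage] = {"n_markers": len(assoc_rows)}
    except Exception as err:
        report["failed_stage"] = stage
        report["error"] = str(err)
        _write_report(report, config.out_dir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    _write_report(report, config.out_dir)
    log.info("pipeline complete: %s", config.out_dir)
    return report


def _write_report(report: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
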