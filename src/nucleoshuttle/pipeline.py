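"""End-to-end orchestration: simulate -> segment -> quantify -> analyze.

A run is described by a :class:`RunConfig` (loadable from YAML), executes
deterministically from its seed, and writes everything under one output
directory with fixed names: ``records.csv``, ``summary.csv``, ``tests.csv``,
``kinetics.csv`` (when the design has timepoints) and ``manifest.json``
listing every output with a SHA-256 checksum, the config echo and the seed.
Rerunning the same config reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import __version__
from .quantify import CategoryParams, category_fractions, quantify_field
from .readwrite import write_records
from .segmentation import SegParams, segment_nuclei, segment_nucleoli
from .stats import aggregate, anova_two_way, chisq_test, kinetics_summary, significance_stars
from .synthetic import SyntheticSpec, generate_field

logger = logging.getLogger(__name__)

__all__ = ["Condition", "RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending field."""


@dataclass(frozen=True)
class Condition:
    """One experimental arm of a simulated study."""

    genotype: str = "WT"
    treatment: str = "untreated"
    dose: Optional[float] = None
    timepoint: float = 0.0
    enrichment: float = 3.0


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: Union[str, Path] = "run"
    conditions: Sequence[Condition] = (
        Condition(genotype="WT", treatment="untreated", timepoint=0.0, enrichment=3.0),
        Condition(genotype="WT", treatment="H2O2", timepoint=2.0, enrichment=0.6),
    )
    n_replicates: int = 3
    fields_per_replicate: int = 1
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    seg_params: SegParams = field(default_factory=SegParams)
    category_params: CategoryParams = field(default_factory=CategoryParams)
    design_factors: Tuple[str, str] = ("genotype", "timepoint")
    seed: int = 0
    write_images: bool = False

    def validate(self) -> None:
        if self.n_replicates < 1 or self.fields_per_replicate < 1:
            raise ValueError("n_replicates and fields_per_replicate must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        self.spec.validate()
        self.seg_params.validate()
        self.category_params.validate()


def load_config(path: Union[str, Path]) -> RunConfig:
    """Build a RunConfig from a YAML mapping; omitted keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: Dict = {}
    if "conditions" in raw:
        kwargs["conditions"] = tuple(Condition(**c) for c in raw.pop("conditions"))
    if "spec" in raw:
        kwargs["spec"] = SyntheticSpec(**_tuplify(raw.pop("spec")))
    if "seg_params" in raw:
        kwargs["seg_params"] = SegParams(**raw.pop("seg_params"))
    if "category_params" in raw:
        kwargs["category_params"] = CategoryParams(**raw.pop("category_params"))
    if "design_factors" in raw:
        kwargs["design_factors"] = tuple(raw.pop("design_factors"))
    kwargs.update(raw)
    return RunConfig(**kwargs)


def _tuplify(d: Dict) -> Dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.write_images:
        (out_dir / "fields").mkdir(exist_ok=True)
        (out_dir / "masks").mkdir(exist_ok=True)

    records = []
    field_counter = 0
    for ci, cond in enumerate(config.conditions):
        for rep in range(1, config.n_replicates + 1):
            for fi in range(config.fields_per_replicate):
                field_counter += 1
                field_id = f"c{ci}_r{rep}_f{fi}"
                spec = dataclasses.replace(
                    config.spec,
                    enrichment_factor_e=cond.enrichment,
                    seed=config.seed + field_counter,
                )
                try:
                    fld, truth = generate_field(spec)
                except Exception as exc:
                    raise PipelineError(f"simulate failed on field {field_id}: {exc}") from exc
                fld.metadata.genotype = cond.genotype
                fld.metadata.treatment = cond.treatment
                fld.metadata.dose = cond.dose
                fld.metadata.timepoint = cond.timepoint
                fld.metadata.replicate_id = f"rep{rep}"
                fld.metadata.field_id = field_id

                try:
                    nuclei = segment_nuclei(fld.channel("nuclear_dye"), config.seg_params)
                    nucleoli = segment_nucleoli(
                        fld.channel("nucleolar_marker"), nuclei, config.seg_params
                    )
                except Exception as exc:
                    raise PipelineError(f"segment failed on field {field_id}: {exc}") from exc
                try:
                    recs = quantify_field(fld, nuclei, nucleoli, config.category_params)
                except Exception as exc:
                    raise PipelineError(f"quantify failed on field {field_id}: {exc}") from exc
                records.extend(recs)
                n_flagged = sum(1 for r in recs if r.qc_flag != "ok")
                logger.info(
                    "field %s: nuclei=%d nucleoli=%d records=%d flagged=%d",
                    field_id, nuclei.n_labels, nucleoli.n_labels, len(recs), n_flagged,
                )
                if config.write_images:
                    from .readwrite import write_field, write_label_mask

                    write_field(fld, out_dir / "fields" / f"{field_id}.tif")
                    write_label_mask(nuclei, out_dir / "masks" / f"{field_id}_nuclei.tif")
                    write_label_mask(nucleoli, out_dir / "masks" / f"{field_id}_nucleoli.tif")

    records_path = out_dir / "records.csv"
    write_records(records, records_path)
    frame = pd.read_csv(records_path)
    outputs = [records_path] + _analysis_outputs(frame, config.design_factors, out_dir)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "n_fields": field_counter,
        "n_records": len(records),
        "n_records_flagged": int(sum(1 for r in records if r.qc_flag != "ok")),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _analysis_outputs(
    frame: pd.DataFrame,
    design_factors: Sequence[str],
    out_dir: Path,
) -> List[Path]:
    """Write summary.csv, tests.csv and (for time courses) kinetics.csv."""
    out_dir = Path(out_dir)
    grouping = [g for g in dict.fromkeys(design_factors) if g in frame.columns]
    summary = aggregate(frame, grouping)
    summary_path = out_dir / "summary.csv"
    summary.drop(columns=["replicate_means"]).to_csv(summary_path, index=False)

    # hypothesis tests on the design factors
    test_rows: List[Dict] = []
    defined = frame[frame["category"].isin(("strong", "medium", "without"))]
    try:
        counts = (
            defined.assign(condition=defined[grouping].astype(str).agg("|".join, axis=1))
            .groupby("condition")["category"]
            .value_counts()
            .unstack(fill_value=0)
        )
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        if counts.shape[0] >= 2 and counts.shape[1] >= 2:
            chi = chisq_test(counts.to_numpy())
            test_rows.append(
                {
                    "test": "chisq", "term": "condition x category",
                    "statistic": chi.statistic, "df": chi.df, "p": chi.p_value,
                    "stars": significance_stars(chi.p_value),
                }
            )
    except Exception as exc:  # degenerate small designs are not fatal
        logger.warning("chi-square skipped: %s", exc)

    rep_means = (
        frame.dropna(subset=["displayed_ratio"])
        .groupby(grouping + ["replicate_id"], dropna=False, as_index=False)["displayed_ratio"]
        .mean()
    )
    if len(grouping) == 2 and all(rep_means[g].nunique() >= 2 for g in grouping):
        res = anova_two_way(rep_means, "displayed_ratio", grouping[0], grouping[1])
        for term, row in res.table.iterrows():
            if term == "residual":
                continue
            test_rows.append(
                {
                    "test": "anova2", "term": term,
                    "statistic": row["F"], "df": row["df"], "p": row["p"],
                    "stars": significance_stars(row["p"]),
                }
            )
    tests_path = out_dir / "tests.csv"
    pd.DataFrame(
        test_rows, columns=["test", "term", "statistic", "df", "p", "stars"]
    ).to_csv(tests_path, index=False)

    outputs = [summary_path, tests_path]

    # kinetics when the design spans multiple timepoints
    if "timepoint" in frame.columns and frame["timepoint"].nunique() >= 2:
        by_time = aggregate(frame, ["timepoint"])
        kin = kinetics_summary(by_time)
        kin_path = out_dir / "kinetics.csv"
        pd.DataFrame(
            {
                "timepoint": kin.timepoints,
                "grand_mean": kin.grand_means,
                "release_time": kin.release_time,
                "recovery_time": kin.recovery_time,
                "no_release": kin.no_release,
                "no_recovery": kin.no_recovery,
            }
        ).to_csv(kin_path, index=False)
        outputs.append(kin_path)
    return outputs


def _config_echo(config: RunConfig) -> Dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return {
        f.name: enc(getattr(config, f.name)) for f in dataclasses.fields(config)
    }
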