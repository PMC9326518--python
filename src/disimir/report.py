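"""Pipeline orchestration from a config file, plus literature validation.

``run_pipeline`` drives the whole analysis from a flat YAML config and
writes every intermediate artifact (consensus network, influence and
conservation tables, feature table, prediction report) along with a run
log recording the config, package version and seeds.

``literature_validation_summary`` reduces a manually curated annotation
table of false-positive predictions — each marked causal, mentioned in
the literature but not causal, or unmentioned — to per-disease and
pooled percent-causal figures.  Unmentioned miRNAs are excluded from
the denominator, and the aggregate uses pooled counts rather than a
mean of per-disease percentages.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd
import yaml

from importlib.metadata import version as _pkg_version

from .classifier import ModelConfig
from .data_io import write_network
from .model import DisiMiR
from .network_inference import ConsensusConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "literature_validation_summary",
           "read_literature_annotations"]

_REQUIRED_KEYS = ["expression", "annotations", "disease"]

_STATUSES = {"causal", "mentioned_noncausal", "unmentioned"}


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None):
    """Execute the five pipeline stages from a structured config.

    The config (YAML file or dict) must name the expression and
    annotation inputs and the disease; family/FASTA/target paths and
    all tunables are optional.  Returns the fitted results after
    writing all artifacts to ``out_dir`` (default: config key ``out``,
    else ``disimir_report/``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise KeyError(f"config is missing required key {key!r}")

    out = Path(out_dir or config.get("out", "disimir_report"))
    out.mkdir(parents=True, exist_ok=True)

    ccfg = ConsensusConfig(
        threshold=float(config.get("threshold", 0.7)),
        genie3_n_trees=int(config.get("genie3_trees", 100)),
        n_bins=config.get("bins", "auto"),
        genie3_sample_cap=config.get("genie3_sample_cap"),
        seed=int(config.get("seed", 0)),
    )
    mcfg = ModelConfig(
        n_estimators=int(config.get("estimators", 1500)),
        n_splits=int(config.get("splits", 100)),
        min_false_positives=int(config.get("min_fp", 10)),
        seed=int(config.get("seed", 0)),
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                from exc

    model = stage(
        "load-inputs", DisiMiR.from_files,
        config["expression"], config["annotations"], config["disease"],
        family_path=config.get("families"),
        fasta_path=config.get("fasta"),
        target_path=config.get("targets"),
        delimiter=config.get("delimiter", "\t"),
        consensus_config=ccfg, model_config=mcfg,
        min_causal=int(config.get("min_causal", 20)),
    )
    results = stage("fit", model.fit,
                    keep_per_method=bool(config.get("write_per_method",
                                                    False)))

    write_network(results.consensus, out / "consensus_network.tsv")
    for name, net in results.per_method_networks.items():
        write_network(net, out / f"network_{name}.tsv")
    results.influence.to_csv(out / "influence.tsv", sep="\t",
                             float_format="%.6f")
    results.conservation.to_csv(out / "conservation.tsv", sep="\t",
                                float_format="%.6f")
    results.feature_table.rename_axis("mirna").to_csv(
        out / "features.tsv", sep="\t", float_format="%.6f")
    results.save(out)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"disimir version: {_pkg_version('disimir')}\n")
        fh.write(f"config: {dict(sorted(config.items()))}\n")
        fh.write(f"seed: {ccfg.seed}\n")
        fh.write(results.summary() + "\n")
    return results


def read_literature_annotations(path: str | Path) -> pd.DataFrame:
    """Read a (miRNA, disease, status) literature-annotation TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().casefold(): c for c in df.columns}
    required = {"mirna", "disease", "status"}
    if not required <= set(cols):
        raise ValueError(
            f"annotation table needs columns {sorted(required)}")
    df = df.rename(columns={cols[k]: k for k in required})
    df["status"] = df["status"].astype(str).str.strip().str.casefold()
    bad = set(df["status"]) - _STATUSES
    if bad:
        raise ValueError(
            f"unknown status values {sorted(bad)}; allowed: "
            f"{sorted(_STATUSES)}")
    return df


def literature_validation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Percent of literature-mentioned false positives found causal.

    Per disease and pooled over all rows: 100 * causal /
    (causal + mentioned_noncausal); ``unmentioned`` rows never enter
    the denominator.  A disease whose rows are all unmentioned reports
    NA.  Display rounding is one decimal, half away from zero.
    """
    if "status" not in table.columns:
        raise ValueError("table must have a 'status' column")
    rows = []
    groups = list(table.groupby("disease", sort=False))
    groups.append(("all diseases", table))
    for disease, sub in groups:
        causal = int((sub["status"] == "causal").sum())
        mentioned = int((sub["status"] == "mentioned_noncausal").sum())
        unmentioned = int((sub["status"] == "unmentioned").sum())
        denom = causal + mentioned
        if denom == 0:
            pct = float("nan")
        else:
            pct = math.floor(1000.0 * causal / denom + 0.5) / 10.0
        rows.append((disease, causal, mentioned, pct, unmentioned,
                     len(sub)))
    return pd.DataFrame(
        rows, columns=["disease", "causal", "mentioned_noncausal",
                       "percent_causal", "unmentioned", "total"])
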