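"""Model-level interface over the whole pipeline.

:class:`DisiMiR` bundles the four inputs and the configuration;
``fit()`` runs network inference, influence scoring, feature assembly
and the repeated-split boosted classifier, returning a
:class:`DisiMiRResults` with the per-miRNA probabilities, the AUCs and
their CI, the decision threshold, confusion matrix, enrichment p-value
and feature importances, plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classifier import ModelConfig, PredictionReport, evaluate
from .conservation import conservation_frame, conservation_table
from .data_io import (DiseaseAnnotation, ExpressionMatrix, FamilyDB,
                      TargetCounts, read_disease_annotations,
                      read_expression_matrix, read_family_db,
                      read_target_counts)
from .features import build_feature_table
from .influence import influence_table
from .network_inference import (ConsensusConfig, WeightedDirectedNetwork,
                                consensus_network)

__all__ = ["DisiMiR", "DisiMiRResults"]


@dataclass
class DisiMiRResults:
    """Fit results: estimates, uncertainties and diagnostics."""

    report: PredictionReport
    feature_table: pd.DataFrame
    consensus: WeightedDirectedNetwork
    influence: pd.DataFrame
    conservation: pd.DataFrame
    per_method_networks: dict[str, WeightedDirectedNetwork] = field(
        default_factory=dict, repr=False)

    @property
    def probabilities(self) -> pd.Series:
        """Mean out-of-fold causality probability per miRNA."""
        return self.report.probabilities

    @property
    def auc(self) -> float:
        return self.report.auc

    @property
    def auc_ci(self) -> tuple[float, float]:
        return self.report.auc_ci

    @property
    def associated_only_auc(self) -> float:
        return self.report.associated_only_auc

    @property
    def predictions(self) -> pd.DataFrame:
        """Per-miRNA probability, label and thresholded prediction."""
        table = self.feature_table
        return pd.DataFrame({
            "probability": self.report.probabilities,
            "label": table["label"],
            "is_associated": table["is_associated"],
            "predicted": (self.report.probabilities
                          >= self.report.threshold).astype(int),
        })

    def false_positives(self) -> list[str]:
        """Predicted-causal miRNAs without a curated causal label —
        the model's hypotheses for literature follow-up."""
        p = self.predictions
        return list(p.index[(p["predicted"] == 1) & (p["label"] == 0)])

    def summary(self) -> str:
        r = self.report
        tn, fp, fn, tp = r.confusion
        lines = [
            "DisiMiR causal-miRNA prediction results",
            "=" * 47,
            f"miRNAs scored:          {len(self.feature_table)}",
            f"causal (curated):       {int(self.feature_table['label'].sum())}",
            f"disease-associated:     "
            f"{int(self.feature_table['is_associated'].sum())}",
            f"AUC:                    {r.auc:.3f} "
            f"(95% CI {r.auc_ci[0]:.3f}, {r.auc_ci[1]:.3f})",
            f"associated-only AUC:    {r.associated_only_auc:.3f}",
            f"decision threshold:     {r.threshold:.3f}",
            f"confusion (TN FP FN TP): {tn} {fp} {fn} {tp}",
            f"hypergeometric p:       {r.hypergeom_p:.3g}",
            "feature importances:",
        ]
        for name, imp in r.feature_importances.items():
            lines.append(f"  {name:20s} {imp:.3f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write predictions, metrics and importances as TSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.predictions.rename_axis("mirna").to_csv(
            out / "predictions.tsv", sep="\t", float_format="%.6f")
        self.report.metrics_frame().to_csv(
            out / "metrics.tsv", sep="\t", index=False)
        pd.Series(self.report.feature_importances, name="importance") \
            .rename_axis("feature").to_csv(
                out / "importances.tsv", sep="\t", float_format="%.6f")


class DisiMiR:
    """Disease-causal miRNA predictor.

    Parameters
    ----------
    expression : ExpressionMatrix
        Pre-normalized miRNA x sample expression values.
    annotation : DiseaseAnnotation
        Disease-associated and causal miRNA sets (HMDD-style).
    families : FamilyDB, optional
        miRNA family definitions with mature sequences; omitted means
        the conservation feature is all zeros.
    target_counts : TargetCounts, optional
        Predicted mRNA-target counts; omitted means all zeros.
    consensus_config, model_config : optional
        Tunables of the network-inference and classification stages.
    min_causal : int
        Minimum number of causal miRNAs required to train (default 20).
    """

    def __init__(self, expression: ExpressionMatrix,
                 annotation: DiseaseAnnotation,
                 families: FamilyDB | None = None,
                 target_counts: TargetCounts | None = None,
                 consensus_config: ConsensusConfig | None = None,
                 model_config: ModelConfig | None = None,
                 min_causal: int = 20):
        self.expression = expression
        self.annotation = annotation
        self.families = families or FamilyDB()
        self.target_counts = target_counts or TargetCounts()
        self.consensus_config = consensus_config or ConsensusConfig()
        self.model_config = model_config or ModelConfig()
        self.min_causal = min_causal

    @classmethod
    def from_files(cls, expression_path: str | Path,
                   annotation_path: str | Path, disease_name: str,
                   family_path: str | Path | None = None,
                   fasta_path: str | Path | None = None,
                   target_path: str | Path | None = None,
                   delimiter: str = "\t", **kwargs) -> "DisiMiR":
        """Build a model straight from the on-disk input files."""
        expr = read_expression_matrix(expression_path, delimiter)
        ann = read_disease_annotations(annotation_path, disease_name)
        fam = read_family_db(family_path, fasta_path) \
            if family_path and fasta_path else None
        targets = read_target_counts(target_path) if target_path else None
        return cls(expr, ann, fam, targets, **kwargs)

    def fit(self, keep_per_method: bool = False) -> DisiMiRResults:
        """Run the full pipeline and return the results object."""
        net, parts = consensus_network(self.expression,
                                       self.consensus_config,
                                       return_parts=True)
        infl = influence_table(net, self.annotation)
        cons = conservation_table(self.families, net.mirna_ids)
        table = build_feature_table(infl, cons, self.target_counts,
                                    self.annotation,
                                    min_causal=self.min_causal)
        report = evaluate(table, self.model_config)
        return DisiMiRResults(
            report=report,
            feature_table=table,
            consensus=net,
            influence=infl.to_frame(),
            conservation=conservation_frame(cons),
            per_method_networks=parts if keep_per_method else {},
        )
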