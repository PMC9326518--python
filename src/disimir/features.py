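"""Per-miRNA feature matrix assembly.

One row per consensus-network miRNA (isolated nodes included, so the
confusion-matrix totals can equal the platform's full miRNA count),
with the four model features in a fixed column order:

    disease_influence, network_influence, conservation, n_targets

plus the causality label and the disease-association flag.
"""

from __future__ import annotations

import logging

import pandas as pd

from .conservation import ConservationRecord
from .data_io import DiseaseAnnotation, TargetCounts
from .influence import InfluenceTable

logger = logging.getLogger(__name__)

__all__ = ["FeatureTable", "build_feature_table", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ["disease_influence", "network_influence",
                   "conservation", "n_targets"]

#: pandas DataFrame indexed by miRNA with FEATURE_COLUMNS plus
#: ``is_associated`` (bool) and ``label`` (1 = causal, 0 = non-causal).
FeatureTable = pd.DataFrame


def build_feature_table(infl: InfluenceTable,
                        cons: list[ConservationRecord],
                        targets: TargetCounts,
                        ann: DiseaseAnnotation,
                        min_causal: int = 20) -> FeatureTable:
    """Assemble the model's training table.

    The row universe is the set of consensus-network miRNAs (the keys of
    the influence table); causal miRNAs absent from the network are
    logged and dropped.  Missing conservation or target entries default
    to 0.  Fewer than ``min_causal`` causal rows raises: diseases with a
    handful of curated causal miRNAs do not support a statistically
    meaningful classifier.
    """
    universe = list(infl.whole_network)
    cons_by_name = {r.mirna: r.conservation for r in cons}
    rows = []
    for m in universe:
        rows.append({
            "mirna": m,
            "disease_influence": infl.disease_specific[m],
            "network_influence": infl.whole_network[m],
            "conservation": cons_by_name.get(m, 0.0),
            "n_targets": float(targets.counts.get(m, 0)),
            "is_associated": m in ann.associated,
            "label": int(m in ann.causal),
        })
    table = pd.DataFrame(rows).set_index("mirna")

    missing_causal = ann.causal - set(universe)
    if missing_causal:
        logger.info("%d causal miRNA(s) not in the network, excluded: %s",
                    len(missing_causal), sorted(missing_causal)[:10])
    n_causal = int(table["label"].sum())
    if n_causal < min_causal:
        raise ValueError(
            f"only {n_causal} causal miRNAs in the feature table "
            f"(minimum {min_causal}); too few positive examples to train "
            "a meaningful classifier")
    return table[FEATURE_COLUMNS + ["is_associated", "label"]]
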