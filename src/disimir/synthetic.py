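"""Self-contained synthetic fixtures with planted regulatory structure.

The generator emulates the pipeline's four inputs at once:

* an expression matrix in which a few hub miRNAs each drive a block of
  target miRNAs linearly (plus Gaussian noise), with all remaining
  miRNAs pure noise — a dependence every one of the five inference
  methods can detect;
* causality labels linked to hub membership (probability
  ``causal_link_strength`` for hubs, a 5% baseline otherwise) and, via
  the family construction below, to conservation;
* an associated set that contains the causal miRNAs, each hub's
  regulated targets with probability 0.6, and random extras;
* miRNA families: every causal miRNA gets a family whose member
  sequences are its own sequence mutated at rate ``family_divergence``;
  non-causal miRNAs get a smaller family with low probability;
* predicted-target counts proportional to planted out-degree plus
  Poisson noise.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (DiseaseAnnotation, ExpressionMatrix, FamilyDB,
                      TargetCounts)

__all__ = ["SyntheticSpec", "generate_fixture", "write_fixture"]

_RNA = np.array(list("ACGU"))


@dataclass
class SyntheticSpec:
    """Parameters of the planted-hub study design."""

    n_mirnas: int = 300
    n_samples: int = 60
    n_hubs: int = 10
    targets_per_hub: int = 8
    noise_sd: float = 0.3
    causal_link_strength: float = 0.8
    baseline_causal_rate: float = 0.05
    family_divergence: float = 0.1
    hub_amplitude: float = 0.85
    seq_length: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_samples, self.n_hubs,
               self.targets_per_hub) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_hubs * self.targets_per_hub >= self.n_mirnas:
            raise ValueError(
                "n_hubs * targets_per_hub must be < n_mirnas")
        if not 0.0 <= self.causal_link_strength <= 1.0:
            raise ValueError("causal_link_strength must be in [0, 1]")
        if self.noise_sd < 0 or self.family_divergence < 0:
            raise ValueError("rates must be non-negative")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RNA, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(_RNA))
    return "".join(out)


def generate_fixture(spec: SyntheticSpec
                     ) -> tuple[ExpressionMatrix, DiseaseAnnotation,
                                FamilyDB, TargetCounts, list[str]]:
    """Generate all four pipeline inputs plus the ground-truth hub list."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_mirnas, spec.n_samples
    names = [f"syn-mir-{i:04d}" for i in range(m)]

    hubs = list(range(spec.n_hubs))
    targets_of: dict[int, list[int]] = {}
    next_target = spec.n_hubs
    values = np.zeros((m, n))
    for h in hubs:
        values[h] = rng.normal(0.0, spec.hub_amplitude, size=n)
        tgts = list(range(next_target, next_target + spec.targets_per_hub))
        next_target += spec.targets_per_hub
        targets_of[h] = tgts
        for t in tgts:
            slope = rng.uniform(0.9, 1.1)
            values[t] = slope * values[h] + rng.normal(
                0.0, spec.noise_sd, size=n)
    for i in range(next_target, m):
        values[i] = rng.normal(0.0, 1.0, size=n)
    # shift to non-negative normalized-expression-like units
    values = values - values.min() + 1.0
    expr = ExpressionMatrix(names, [f"sample{j:02d}" for j in range(n)],
                            values)

    # correlation contract: hubs must out-correlate random pairs
    for h in hubs:
        t = targets_of[h][0]
        r_linked = abs(np.corrcoef(values[h], values[t])[0, 1])
        i, j = rng.choice(np.arange(next_target, m), size=2, replace=False)
        r_rand = abs(np.corrcoef(values[i], values[j])[0, 1])
        if r_linked <= r_rand:
            raise RuntimeError(
                "planted hub-target correlation does not exceed a random "
                "pair; increase n_samples or lower noise_sd")

    hub_set = set(hubs)
    causal: set[str] = set()
    for i in range(m):
        p = spec.causal_link_strength if i in hub_set \
            else spec.baseline_causal_rate
        if rng.random() < p:
            causal.add(names[i])
    associated = set(causal)
    for h in hubs:
        for t in targets_of[h]:
            if rng.random() < 0.6:
                associated.add(names[t])
    for i in range(m):
        if rng.random() < 0.2:
            associated.add(names[i])
    ann = DiseaseAnnotation("synthetic disease", associated, causal)

    # families: conservation statistically linked to causality
    db = FamilyDB()
    fam_counter = 0
    for i in range(m):
        name = names[i]
        if name in db.membership:
            continue
        is_causal = name in causal
        if is_causal:
            size = 3 + int(rng.poisson(5))
        elif rng.random() < 0.15:
            size = 1 + int(rng.poisson(1))
        else:
            continue
        fam_id = f"synfam-{fam_counter:04d}"
        fam_counter += 1
        base = _random_sequence(rng, spec.seq_length)
        members = {name: base}
        for k in range(size - 1):
            members[f"{name}-rel{k}"] = _mutate(rng, base,
                                                spec.family_divergence)
        db.families[fam_id] = members
        for member in members:
            db.membership[member] = fam_id

    out_degree = {names[h]: len(targets_of[h]) for h in hubs}
    counts = {}
    for i in range(m):
        deg = out_degree.get(names[i], 0)
        counts[names[i]] = int(20 * deg + rng.poisson(15))
    targets = TargetCounts(counts)

    return expr, ann, db, targets, [names[h] for h in hubs]


def write_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the generated fixture as the pipeline's on-disk input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, db, targets, hub_names = generate_fixture(spec)

    paths = {
        "expression": out / "expression.tsv",
        "annotations": out / "annotations.tsv",
        "families": out / "mifam.dat",
        "fasta": out / "mature.fa",
        "targets": out / "target_counts.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }

    expr.to_frame().rename_axis("miRNA").to_csv(paths["expression"], sep="\t")

    with open(paths["annotations"], "w") as fh:
        fh.write("mirna\tdisease\tcausality\n")
        for name in sorted(ann.associated):
            flag = "yes" if name in ann.causal else "no"
            fh.write(f"{name}\t{ann.disease_name}\t{flag}\n")

    with open(paths["families"], "w") as fh, \
            open(paths["fasta"], "w") as fa:
        for fam_id, members in db.families.items():
            fh.write(f"ID {fam_id}\n")
            for i, (name, seq) in enumerate(members.items()):
                fh.write(f"MI MI{i:07d} {name}\n")
                fa.write(f">{name}\n{seq}\n")
            fh.write("//\n")

    with open(paths["targets"], "w") as fh:
        fh.write("miRNA\tn_targets\n")
        for name, count in targets.counts.items():
            fh.write(f"{name}\t{count}\n")

    with open(paths["ground_truth"], "w") as fh:
        fh.write("mirna\tis_hub\n")
        hubs = set(hub_names)
        for name in expr.mirna_ids:
            fh.write(f"{name}\t{int(name in hubs)}\n")
    return paths
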