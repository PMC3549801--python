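"""Synthetic benchmarks with planted regulatory structure.

A scenario plants exact k-mer motifs into the promoters of gene modules
and gives each module a shared latent expression profile, so that the
full discovery pipeline (counting, co-expression network, enrichment,
bipartite network) has a known ground truth to recover.  Defaults model
a genome of 1000 promoters of 500 bp with three 30-gene modules, each
carrying one planted 6-mer at 90% plant probability against a 5%
background insertion rate, and 60 arrays with unit module effect and
Gaussian noise (sd 0.3) — strong but not saturated module co-expression
(expected within-module correlation about 1/(1+0.09) ~ 0.92).

Planting overwrites a window of the background sequence (never inserts),
so all promoters keep length L.  Background promoters can still contain
a planted word by chance, which is the realistic null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .coexpression import ExpressionMatrix
from .kmer_counts import PromoterRecord

BASES = "ACGT"

DEFAULT_MODULES = [
    (30, ["ACGCGT"], 0.9),
    (30, ["GATAAG"], 0.9),
    (30, ["AAGGGG"], 0.9),
]


@dataclass
class SyntheticScenario:
    """Full parameter record for one synthetic benchmark."""

    m: int = 1000                     # background promoter count
    L: int = 500                      # promoter length (bp)
    n: int = 300                      # target genes (first n of the m)
    modules: list[tuple[int, list[str], float]] = field(
        default_factory=lambda: [tuple(t) for t in DEFAULT_MODULES]
    )                                 # (size, planted motifs, plant_prob)
    background_rate: float = 0.05     # planted-motif insertion rate elsewhere
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_arrays: int = 60
    module_effect: float = 1.0        # amplitude of the shared latent factor
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if not all(0 <= p <= 1 for p in self.base_composition):
            raise ValueError("base_composition entries must be probabilities")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be a probability")
        if sum(size for size, _, _ in self.modules) > self.n or self.n > self.m:
            raise ValueError("module sizes must sum <= n <= m")

    def gene_ids(self) -> list[str]:
        width = len(str(self.m))
        return [f"g{i + 1:0{width}d}" for i in range(self.m)]

    def target_ids(self) -> list[str]:
        return self.gene_ids()[: self.n]

    def module_assignments(self) -> list[tuple[str, list[str]]]:
        """(gene_id, planted motifs of its module) for every module gene."""
        ids = self.gene_ids()
        out = []
        start = 0
        for size, motifs, _ in self.modules:
            for g in ids[start : start + size]:
                out.append((g, list(motifs)))
            start += size
        return out

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def generate_promoters(
    scn: SyntheticScenario,
) -> tuple[list[PromoterRecord], list[tuple[str, str]]]:
    """Background promoters with motifs planted into module genes.

    Returns the promoter records and the ground-truth (module gene,
    planted motif) pairs.  Module promoters receive each of their
    module's motifs with probability ``plant_prob``; every other
    promoter receives each planted motif with probability
    ``background_rate``.  Plants overwrite disjoint windows.
    """
    rng = np.random.default_rng(scn.seed)
    all_motifs = sorted({m for _, motifs, _ in scn.modules for m in motifs})
    for m in all_motifs:
        if len(m) > scn.L:
            raise ValueError(f"motif {m} longer than promoter length {scn.L}")
    ids = scn.gene_ids()
    module_of = {g: motifs for g, motifs in scn.module_assignments()}
    plant_prob: dict[str, float] = {}
    start = 0
    for size, motifs, prob in scn.modules:
        for g in ids[start : start + size]:
            plant_prob[g] = prob
        start += size

    base = np.array(list(BASES))
    seqs = rng.choice(base, size=(scn.m, scn.L), p=list(scn.base_composition))
    truth: list[tuple[str, str]] = []
    for g, motifs in module_of.items():
        truth.extend((g, m) for m in motifs)
    for i, g in enumerate(ids):
        to_plant = []
        for m in all_motifs:
            if g in module_of and m in module_of[g]:
                if rng.random() < plant_prob[g]:
                    to_plant.append(m)
            elif rng.random() < scn.background_rate:
                to_plant.append(m)
        if not to_plant:
            continue
        if sum(len(m) for m in to_plant) > scn.L:
            raise ValueError("too many planted motifs to fit in one promoter")
        occupied: list[tuple[int, int]] = []
        for m in to_plant:
            for _attempt in range(1000):
                pos = int(rng.integers(0, scn.L - len(m) + 1))
                span = (pos, pos + len(m))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    occupied.append(span)
                    seqs[i, span[0]:span[1]] = list(m)
                    break
            else:
                raise ValueError("could not place planted motif without overlap")
    records = [PromoterRecord(g, "".join(row)) for g, row in zip(ids, seqs)]
    return records, truth


def generate_expression(scn: SyntheticScenario) -> ExpressionMatrix:
    """Module-structured log-ratio expression over the n target genes.

    Each module draws one latent profile (standard normal per array);
    module genes are module_effect * latent + N(0, noise_sd) noise; all
    other target genes are pure N(0, noise_sd) noise.
    """
    if scn.n_arrays < 3:
        raise ValueError("need n_arrays >= 3 for downstream correlations")
    # offset stream so expression is independent of the promoter draws
    rng = np.random.default_rng((scn.seed, 1))
    ids = scn.target_ids()
    values = rng.normal(0.0, scn.noise_sd, size=(scn.n, scn.n_arrays))
    start = 0
    for size, _motifs, _prob in scn.modules:
        latent = rng.standard_normal(scn.n_arrays)
        values[start : start + size] += scn.module_effect * latent
        start += size
    arrays = [f"array{a + 1:03d}" for a in range(scn.n_arrays)]
    return ExpressionMatrix(ids, arrays, values)


def generate_reference_network(scn: SyntheticScenario) -> list[tuple[str, str]]:
    """Module cliques: every within-module gene pair, sorted."""
    edges = []
    start = 0
    ids = scn.gene_ids()
    for size, _motifs, _prob in scn.modules:
        members = ids[start : start + size]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.append((members[i], members[j]))
        start += size
    return sorted(edges)


def write_scenario(scn: SyntheticScenario, out_dir) -> dict[str, Path]:
    """Materialize promoters.fasta, expr.tsv, truth.tsv, reference.tsv,
    scenario.json under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "promoters": out / "promoters.fasta",
        "expr": out / "expr.tsv",
        "truth": out / "truth.tsv",
        "reference": out / "reference.tsv",
        "scenario": out / "scenario.json",
    }
    records, truth = generate_promoters(scn)
    with open(paths["promoters"], "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n{rec.sequence}\n")
    generate_expression(scn).to_tsv(paths["expr"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tmotif\n")
        for g, m in sorted(truth):
            fh.write(f"{g}\t{m}\n")
    with open(paths["reference"], "w") as fh:
        for a, b in generate_reference_network(scn):
            fh.write(f"{a}\t{b}\n")
    scn.to_json(paths["scenario"])
    return paths


SMALL_PRESET = dict(
    m=60, L=80, n=24,
    modules=[(8, ["ACGCGT"], 1.0), (8, ["GATAAG"], 1.0)],
    background_rate=0.05, n_arrays=20, module_effect=1.0, noise_sd=0.2,
)


def preset_scenario(name: str, seed: int = 0) -> SyntheticScenario:
    if name == "recovery":
        return SyntheticScenario(seed=seed)
    if name == "small":
        return SyntheticScenario(seed=seed, **SMALL_PRESET)
    raise ValueError(f"unknown preset {name!r}; use 'small' or 'recovery'")
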