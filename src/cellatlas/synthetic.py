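"""Synthetic inputs with known ground truth.

Two generators cover everything the downstream stages consume:

* :func:`simulate_atlas` — one- or two-species UMI matrices with shared
  latent cluster programs, planted marker genes, an orthologue map,
  replicate-jittered cluster compositions with planted phenotype
  effects, and a mitochondrial rate share.
* :func:`simulate_sam` — spliced alignment records over a small genome
  with planted good/bad junctions, for exercising the read filter.

Counts are multinomial conditional on per-cell totals drawn
log-normally, so library-size normalization is exact by construction.
Replicate variation enters as Dirichlet jitter of the composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CompositionTable, UmiMatrix

__all__ = ["AtlasSimConfig", "GroundTruth", "simulate_atlas", "SamSim", "simulate_sam"]

SPECIES = ("sp1", "sp2")


@dataclass
class AtlasSimConfig:
    """Parameters of the two-species atlas simulation.

    ``phenotypes`` maps phenotype label → number of replicates (e.g. the
    default emulates a 4-phenotype, 17-sample design). ``planted_effects``
    maps cluster label → {phenotype: abundance multiplier}; omitted
    entries default to 1.0.
    """

    n_species: int = 2
    n_clusters: int = 8
    n_genes: int = 600
    frac_orthologous: float = 0.8
    n_marker_genes_per_cluster: int = 20
    marker_fold: float = 8.0
    phenotypes: Mapping[str, int] = field(
        default_factory=lambda: {"worker": 5, "queen": 4, "gyne": 4, "male": 4}
    )
    cells_per_replicate: int = 300
    base_composition: Sequence[float] | None = None
    planted_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    mito_genes: int = 10
    mito_rate_share: float = 0.005
    mean_umi_per_cell: float = 2000.0
    dispersion: float = 0.3
    replicate_concentration: float = 400.0
    program_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species not in (1, 2):
            raise ValueError("n_species must be 1 or 2")
        if not 0.0 <= self.frac_orthologous <= 1.0:
            raise ValueError("frac_orthologous must be in [0, 1]")
        if self.n_marker_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("marker genes exceed gene count")
        if self.base_composition is None:
            self.base_composition = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.base_composition = np.asarray(self.base_composition, dtype=float)
        if self.base_composition.size != self.n_clusters:
            raise ValueError("base_composition must have one entry per cluster")
        if abs(self.base_composition.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if (self.base_composition <= 0).any():
            raise ValueError("base_composition entries must be positive")
        labels = set(self.cluster_labels)
        for cl, eff in self.planted_effects.items():
            if cl not in labels:
                raise ValueError(f"planted effect for unknown cluster {cl!r}")
            for mult in eff.values():
                if mult <= 0:
                    raise ValueError("abundance multipliers must be > 0")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be positive")
        if self.mean_umi_per_cell <= 0 or self.dispersion <= 0:
            raise ValueError("mean_umi_per_cell and dispersion must be positive")
        if not 0.0 <= self.mito_rate_share < 1.0:
            raise ValueError("mito_rate_share must be in [0, 1)")

    @property
    def cluster_labels(self) -> list[str]:
        return [f"c{k}" for k in range(self.n_clusters)]

    def gene_ids(self, species: str) -> pd.Index:
        regular = [f"{species}_g{i:05d}" for i in range(self.n_genes)]
        mito = [f"{species}_mt{i}" for i in range(self.mito_genes)]
        return pd.Index(regular + mito)


@dataclass
class GroundTruth:
    """Planted structure of a simulated atlas.

    All identifiers refer to generated cluster labels / gene ids only.
    """

    homolog_pairs: set[tuple[str, str]]
    true_markers: dict[str, dict[str, set[str]]]
    affected_clusters: set[str]
    ortho_pairs: set[tuple[str, str]]
    mito_genes: dict[str, set[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "homolog_pairs": sorted(map(list, self.homolog_pairs)),
            "true_markers": {
                sp: {cl: sorted(genes) for cl, genes in per.items()}
                for sp, per in self.true_markers.items()
            },
            "affected_clusters": sorted(self.affected_clusters),
            "ortho_pairs": sorted(map(list, self.ortho_pairs)),
            "mito_genes": {sp: sorted(g) for sp, g in self.mito_genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            homolog_pairs={tuple(p) for p in payload["homolog_pairs"]},
            true_markers={
                sp: {cl: set(genes) for cl, genes in per.items()}
                for sp, per in payload["true_markers"].items()
            },
            affected_clusters=set(payload["affected_clusters"]),
            ortho_pairs={tuple(p) for p in payload["ortho_pairs"]},
            mito_genes={sp: set(g) for sp, g in payload["mito_genes"].items()},
        )


def _cluster_rates(config: AtlasSimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-species K × (genes + mito) multinomial rate matrices."""
    g, m = config.n_genes, config.mito_genes
    n_ortho = int(round(config.frac_orthologous * g))
    base = {SPECIES[0]: rng.lognormal(0.0, 1.0, g)}
    if config.n_species == 2:
        other = rng.lognormal(0.0, 1.0, g)
        noise = rng.lognormal(0.0, config.program_noise, g)
        shared = np.arange(g) < n_ortho
        base[SPECIES[1]] = np.where(shared, base[SPECIES[0]] * noise, other)

    nm = config.n_marker_genes_per_cluster
    rates: dict[str, np.ndarray] = {}
    for species in SPECIES[: config.n_species]:
        r = np.tile(base[species], (config.n_clusters, 1))
        for k in range(config.n_clusters):
            r[k, k * nm : (k + 1) * nm] *= config.marker_fold
        if m > 0:
            share = config.mito_rate_share
            mito_total = share / (1.0 - share) * r.sum(axis=1) if share > 0 else np.zeros(
                config.n_clusters
            )
            mito = np.repeat(mito_total[:, None] / max(m, 1), m, axis=1)
            r = np.hstack([r, mito])
        rates[species] = r / r.sum(axis=1, keepdims=True)
    return rates


def simulate_atlas(
    config: AtlasSimConfig,
) -> tuple[dict[str, UmiMatrix], CompositionTable, GroundTruth]:
    """Simulate UMI matrices, a composition table and the planted truth.

    Returns one :class:`UmiMatrix` per species (keys ``sp1``/``sp2``), the
    :class:`CompositionTable` of the first species, and the
    :class:`GroundTruth`. Output is fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rates = _cluster_rates(config, rng)
    labels = config.cluster_labels
    k = config.n_clusters

    multipliers: dict[str, np.ndarray] = {}
    for ph in config.phenotypes:
        mult = np.ones(k)
        for i, cl in enumerate(labels):
            mult[i] = config.planted_effects.get(cl, {}).get(ph, 1.0)
        multipliers[ph] = mult

    matrices: dict[str, UmiMatrix] = {}
    for species in SPECIES[: config.n_species]:
        blocks: list[np.ndarray] = []
        meta: list[tuple[str, str, str, str]] = []
        for ph, n_reps in config.phenotypes.items():
            expected = config.base_composition * multipliers[ph]
            expected = expected / expected.sum()
            for rep in range(1, n_reps + 1):
                sample = f"{species}_{ph}{rep}"
                comp = rng.dirichlet(config.replicate_concentration * expected)
                assignment = rng.choice(k, size=config.cells_per_replicate, p=comp)
                sigma = config.dispersion
                mu = np.log(config.mean_umi_per_cell) - sigma**2 / 2.0
                totals = np.maximum(
                    1, np.rint(rng.lognormal(mu, sigma, config.cells_per_replicate))
                ).astype(np.int64)
                counts = np.zeros(
                    (config.cells_per_replicate, rates[species].shape[1]), dtype=np.int64
                )
                for kk in range(k):
                    idx = np.flatnonzero(assignment == kk)
                    if idx.size:
                        counts[idx] = rng.multinomial(totals[idx], rates[species][kk])
                blocks.append(counts)
                for i, a in enumerate(assignment):
                    meta.append((f"{sample}_cell{i:04d}", sample, ph, labels[a]))
        obs = pd.DataFrame(
            meta, columns=["cell", "sample", "phenotype", "cluster"]
        ).set_index("cell")
        obs["species"] = species
        matrices[species] = UmiMatrix(
            sp.csr_matrix(np.vstack(blocks)), config.gene_ids(species), obs
        )

    table = CompositionTable.from_umi(matrices[SPECIES[0]])

    nm = config.n_marker_genes_per_cluster
    true_markers = {
        species: {
            labels[kk]: set(config.gene_ids(species)[kk * nm : (kk + 1) * nm])
            for kk in range(k)
        }
        for species in SPECIES[: config.n_species]
    }
    affected = {
        cl
        for cl, eff in config.planted_effects.items()
        if any(mult != 1.0 for mult in eff.values())
    }
    n_ortho = int(round(config.frac_orthologous * config.n_genes))
    if config.n_species == 2:
        ortho_pairs = {
            (f"sp1_g{i:05d}", f"sp2_g{i:05d}") for i in range(n_ortho)
        }
        homolog_pairs = {(cl, cl) for cl in labels}
    else:
        ortho_pairs = set()
        homolog_pairs = set()
    truth = GroundTruth(
        homolog_pairs=homolog_pairs,
        true_markers=true_markers,
        affected_clusters=affected,
        ortho_pairs=ortho_pairs,
        mito_genes={
            species: set(config.gene_ids(species)[config.n_genes :])
            for species in SPECIES[: config.n_species]
        },
    )
    return matrices, table, truth


# ---------------------------------------------------------------------------
# SAM / genome fixture
# ---------------------------------------------------------------------------

_CANONICAL = [("GT", "AG"), ("GC", "AG"), ("AT", "AC")]
# donor/acceptor pairs that are canonical on neither genomic orientation
_BAD_MOTIFS = [("AA", "TT"), ("CC", "GG"), ("GA", "TC")]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SamSim:
    """A simulated SAM fixture with its genome and expected filter outcome."""

    sam_text: str
    genome: dict[str, str]
    expected_pass: set[str]
    read_classes: dict[str, str]

    def write(self, sam_path: str | Path, fasta_path: str | Path) -> None:
        Path(sam_path).write_text(self.sam_text)
        with open(fasta_path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def simulate_sam(
    n_reads: int,
    frac_multimapped: float = 0.0,
    frac_long_gap: float = 0.0,
    frac_noncanonical: float = 0.0,
    seed: int = 0,
    long_gap_length: int = 60_000,
) -> SamSim:
    """Emit reads of four classes over a genome with planted junctions.

    Classes: clean unspliced, clean spliced (canonical motif on either
    orientation, gap ≤ 50 kb), multimapped (``NH > 1``), long-gap
    (``long_gap_length`` > 50 kb), and non-canonical splice motif.
    ``expected_pass`` holds the ids of the clean reads.
    """
    for frac in (frac_multimapped, frac_long_gap, frac_noncanonical):
        if frac < 0:
            raise ValueError("fractions must be non-negative")
    if frac_multimapped + frac_long_gap + frac_noncanonical > 1.0 + 1e-12:
        raise ValueError("class fractions must sum to at most 1")
    if long_gap_length <= 50_000:
        raise ValueError("long_gap_length must exceed 50,000")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")

    rng = np.random.default_rng(seed)
    n_multi = int(round(frac_multimapped * n_reads))
    n_long = int(round(frac_long_gap * n_reads))
    n_bad = int(round(frac_noncanonical * n_reads))
    overshoot = n_multi + n_long + n_bad - n_reads
    if overshoot > 0:  # rounding pushed past the total
        n_bad -= overshoot
    n_ok = n_reads - n_multi - n_long - n_bad

    block = 40
    margin = 10
    # junction templates: (gap, donor, acceptor) written onto the genome
    templates: list[tuple[str, int, str, str]] = []
    for i, (donor, acceptor) in enumerate(_CANONICAL):
        gap = 500 + 700 * i
        templates.append(("ok_fwd", gap, donor, acceptor))
        # same junction seen on the opposite genomic strand
        templates.append(("ok_rev", gap + 101, _revcomp(acceptor), _revcomp(donor)))
    for i in range(3):
        donor, acceptor = _CANONICAL[i]
        templates.append(("long", long_gap_length, donor, acceptor))
    for donor, acceptor in _BAD_MOTIFS:
        templates.append(("bad", 1000, donor, acceptor))

    unspliced_region = 2_000
    pos = unspliced_region
    placed: dict[str, list[tuple[int, int]]] = {"ok": [], "long": [], "bad": []}
    plan: list[tuple[int, int, str, str]] = []  # (start, gap, donor, acceptor)
    for kind, gap, donor, acceptor in templates:
        key = "ok" if kind.startswith("ok") else kind
        placed[key].append((pos, gap))
        plan.append((pos, gap, donor, acceptor))
        pos += block + gap + block + margin
    genome_len = pos + margin
    seq = rng.integers(0, 4, size=genome_len)
    seq = np.frombuffer(b"ACGT", dtype="S1")[seq].astype("U1")
    for start, gap, donor, acceptor in plan:
        gap_start = start + block
        gap_end = gap_start + gap
        seq[gap_start : gap_start + 2] = list(donor)
        seq[gap_end - 2 : gap_end] = list(acceptor)
    genome = {"chr1": "".join(seq)}

    classes = (
        ["ok"] * n_ok + ["multi"] * n_multi + ["long"] * n_long + ["bad"] * n_bad
    )
    rng.shuffle(classes)

    ok_templates = [(p, g) for p, g in placed["ok"]]
    long_templates = [(p, g) for p, g in placed["long"]]
    bad_templates = [(p, g) for p, g in placed["bad"]]

    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:chr1\tLN:{genome_len}",
    ]
    expected_pass: set[str] = set()
    read_classes: dict[str, str] = {}
    counters = {"ok": 0, "long": 0, "bad": 0}
    for i, cls in enumerate(classes):
        read_id = f"r{i:06d}"
        read_classes[read_id] = cls
        nh = 1
        if cls == "multi":
            nh = int(rng.integers(2, 5))
            start = int(rng.integers(0, unspliced_region - 2 * block))
            cigar = f"{2 * block}M"
            read_seq = genome["chr1"][start : start + 2 * block]
        elif cls == "ok" and counters["ok"] % 2 == 0:
            # clean unspliced
            start = int(rng.integers(0, unspliced_region - 2 * block))
            cigar = f"{2 * block}M"
            read_seq = genome["chr1"][start : start + 2 * block]
            expected_pass.add(read_id)
            counters["ok"] += 1
        else:
            pool = {"ok": ok_templates, "long": long_templates, "bad": bad_templates}[cls]
            start, gap = pool[counters[cls] % len(pool)]
            counters[cls] += 1
            cigar = f"{block}M{gap}N{block}M"
            left = genome["chr1"][start : start + block]
            right = genome["chr1"][start + block + gap : start + block + gap + block]
            read_seq = left + right
            if cls == "ok":
                expected_pass.add(read_id)
        lines.append(
            "\t".join(
                [
                    read_id,
                    "0",
                    "chr1",
                    str(start + 1),
                    "255",
                    cigar,
                    "*",
                    "0",
                    "0",
                    read_seq,
                    "I" * len(read_seq),
                    f"NH:i:{nh}",
                ]
            )
        )
    return SamSim("\n".join(lines) + "\n", genome, expected_pass, read_classes)
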