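"""Synthetic inputs for the GWAS-to-network pipeline.

Real studies of this kind run on proprietary farm genotypes and pedigree-based
breeding values, so everything the pipeline consumes can be generated here
with the statistical structure the analysis assumes: a multi-chromosome SNP
map, LD-structured allele dosages, a point-mass mixture of QTL effects with a
controlled heritability, deregressed-EBV-like responses with per-animal
reliabilities, a non-overlapping gene map, and promoter sequences with motif
occurrences planted for known transcription factors.

All generators are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults describe a small pig-like design: a handful of chromosomes, a
    medium-density chip, a 99% zero-effect marker mixture and seven traits of
    moderate heritability, scaled down so a full Gibbs analysis runs on one
    CPU in seconds.
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 20_000_000
    n_markers: int = 1500
    n_animals: int = 300
    n_traits: int = 7
    pi_true: float = 0.99
    h2_per_trait: tuple = (0.36, 0.42, 0.35, 0.42, 0.11, 0.10, 0.08)
    ld_block_bp: int = 250_000
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 60
    n_tfs: int = 8
    motif_length: int = 10
    promoter_length: int = 2000
    seed: int = 0
    # latent-haplotype loading within an LD block; 0 => independent markers
    ld_rho: float = 0.9

    def __post_init__(self):
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_markers": self.n_markers,
            "n_animals": self.n_animals,
            "n_traits": self.n_traits,
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "motif_length": self.motif_length,
            "promoter_length": self.promoter_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 < self.pi_true < 1.0:
            raise ValueError(f"pi_true must lie in (0,1), got {self.pi_true}")
        h2 = tuple(self.h2_per_trait)
        if len(h2) != self.n_traits:
            raise ValueError("h2_per_trait length must equal n_traits")
        for h in h2:
            if not 0.0 < h < 1.0:
                raise ValueError(f"heritability must lie in (0,1), got {h}")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range must be ordered within (0, 0.5], got {self.maf_range}")
        if self.ld_block_bp < 0:
            raise ValueError("ld_block_bp must be >= 0")
        if self.motif_length >= self.promoter_length:
            raise ValueError("motif_length must be shorter than promoter_length")

    @property
    def trait_names(self):
        return [f"T{i + 1}" for i in range(self.n_traits)]

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Genotypes:
    """Allele dosages (animals x markers, values 0/1/2) with row/column ids."""

    animal_ids: list
    marker_ids: list
    dosages: np.ndarray

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TraitTruth:
    """Ground truth for one simulated trait (for recovery checks)."""

    effects: np.ndarray          # length n_markers, mostly zero
    qtl_indices: np.ndarray
    tbv: np.ndarray              # true breeding values, length n_animals
    phenotype: np.ndarray        # tbv + environmental noise


@dataclass
class TrueEffects:
    per_trait: dict = field(default_factory=dict)  # trait name -> TraitTruth


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), salt]))


def simulate_marker_map(cfg: SimConfig) -> pd.DataFrame:
    """Uniform-random marker positions, ~evenly split across chromosomes.

    Returns a frame with columns marker_id, chrom, pos_bp sorted by
    (chromosome, position); positions are unique within a chromosome.
    """
    if cfg.n_markers < cfg.n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = _rng(cfg, 1)
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    rows = []
    for c in range(cfg.n_chromosomes):
        pos = rng.choice(cfg.chrom_length_bp, size=per_chrom[c], replace=False)
        pos.sort()
        for p in pos:
            rows.append((str(c + 1), int(p)))
    mmap = pd.DataFrame(rows, columns=["chrom", "pos_bp"])
    mmap = mmap.sort_values(["chrom", "pos_bp"], key=lambda s: s.astype(int) if s.name == "chrom" else s)
    mmap.insert(0, "marker_id", [f"M{i:05d}" for i in range(len(mmap))])
    return mmap.reset_index(drop=True)


def _ld_blocks(mmap: pd.DataFrame, ld_block_bp: int) -> np.ndarray:
    """Block label per marker: consecutive ld_block_bp windows per chromosome."""
    if ld_block_bp <= 0:
        return np.arange(len(mmap))
    key = mmap["chrom"].astype(str) + ":" + (mmap["pos_bp"] // ld_block_bp).astype(str)
    return pd.factorize(key)[0]


def simulate_genotypes(mmap: pd.DataFrame, cfg: SimConfig) -> Genotypes:
    """LD-structured dosages via a Gaussian-copula latent haplotype signal.

    Each animal carries two latent gametes; within an LD block every marker's
    allele indicator shares the block's latent normal with loading ``ld_rho``,
    so adjacent markers in a block are positively correlated while blocks are
    independent.  Per-marker allele frequencies are uniform in ``maf_range``.
    """
    if len(mmap) == 0:
        raise ValueError("marker map is empty")
    rng = _rng(cfg, 2)
    m = len(mmap)
    n = cfg.n_animals
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresh = norm.ppf(maf)
    blocks = _ld_blocks(mmap, cfg.ld_block_bp)
    n_blocks = blocks.max() + 1
    rho = cfg.ld_rho if cfg.ld_block_bp > 0 else 0.0
    dosage = np.zeros((n, m), dtype=np.int8)
    for _gamete in range(2):
        z_block = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, m))
        latent = rho * z_block[:, blocks] + np.sqrt(1.0 - rho * rho) * eps
        dosage += (latent < thresh[None, :]).astype(np.int8)
    animal_ids = [f"A{i:04d}" for i in range(n)]
    return Genotypes(animal_ids, list(mmap["marker_id"]), dosage)


def simulate_traits(G: Genotypes, cfg: SimConfig):
    """Draw sparse marker effects and reliability-consistent DEBV responses.

    For each trait, round((1-pi_true)*m) markers receive N(0,1) effects,
    rescaled so var(TBV)/var(phenotype) equals the trait heritability; the
    phenotype adds environmental noise accordingly.  The recorded response is
    a DEBV: TBV plus noise of variance sigma_g^2*(1-r2)/r2 for a per-animal
    reliability r2 ~ U(0.1, 0.99].
    """
    if G.n_animals == 0 or G.n_markers == 0:
        raise ValueError("genotypes are empty")
    rng = _rng(cfg, 3)
    m = G.n_markers
    n = G.n_animals
    n_qtl = int(round((1.0 - cfg.pi_true) * m))
    if n_qtl < 1:
        n_qtl = 1
    Zc = G.dosages.astype(float)
    Zc -= Zc.mean(axis=0)
    truth = TrueEffects()
    rows = []
    for t, trait in enumerate(cfg.trait_names):
        h2 = cfg.h2_per_trait[t]
        qtl = np.sort(rng.choice(m, size=n_qtl, replace=False))
        u = np.zeros(m)
        u[qtl] = rng.standard_normal(n_qtl)
        g = Zc @ u
        var_g = g.var()
        if var_g <= 0:
            raise RuntimeError("degenerate genetic variance in simulation")
        # scale so var(g)=h2 and phenotype variance is 1
        scale = np.sqrt(h2 / var_g)
        u *= scale
        g *= scale
        pheno = g + rng.standard_normal(n) * np.sqrt(1.0 - h2)
        rel = rng.uniform(0.1, 0.99, size=n)
        debv = g + rng.standard_normal(n) * np.sqrt(h2 * (1.0 - rel) / rel)
        truth.per_trait[trait] = TraitTruth(u, qtl, g, pheno)
        for i, aid in enumerate(G.animal_ids):
            rows.append((aid, trait, debv[i], rel[i]))
    responses = pd.DataFrame(rows, columns=["animal_id", "trait", "debv", "reliability"])
    return truth, responses


def simulate_gene_annotation(mmap: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals over the simulated genome.

    Genes are distributed round-robin over chromosomes; on each chromosome the
    intervals are placed by sampling gap widths, so they are disjoint by
    construction.  Coordinates are 1-based inclusive.
    """
    if len(mmap) == 0:
        raise ValueError("marker map is empty")
    rng = _rng(cfg, 4)
    chroms = [str(c + 1) for c in range(cfg.n_chromosomes)]
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    rows = []
    gid = 0
    for c, chrom in enumerate(chroms):
        k = int(per_chrom[c])
        if k == 0:
            continue
        lengths = rng.integers(5_000, 50_001, size=k)
        slack = cfg.chrom_length_bp - int(lengths.sum())
        if slack < k:
            raise ValueError("genes cannot fit disjointly in the genome")
        cuts = np.sort(rng.choice(slack, size=k, replace=False))
        start = 0
        prev_cut = 0
        for j in range(k):
            start += cuts[j] - prev_cut
            prev_cut = cuts[j]
            s = start + 1
            e = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"GENE{gid:03d}", chrom, s, e, strand))
            start = e
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return genes.reset_index(drop=True)


@dataclass
class PWM:
    """Position probability matrix over ACGT with a scanning pseudocount."""

    motif_id: str
    matrix: np.ndarray  # shape (length, 4), rows sum to 1
    pseudocount: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be (length>=1) x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.matrix.argmax(axis=1))


def simulate_motifs_and_promoters(genes: pd.DataFrame, cfg: SimConfig):
    """PWMs for the TF genes, one promoter per gene, and the planted truth.

    The first ``n_tfs`` genes act as transcription factors, each with a sharp
    PWM (consensus base probability 0.85).  Each TF's consensus is planted
    into the promoters of a random ~20% subset of genes; ``planted`` maps the
    TF gene id to {target gene id: 1-based plant position}.
    """
    if cfg.motif_length >= cfg.promoter_length:
        raise ValueError("motif longer than promoter")
    if cfg.n_tfs > len(genes):
        raise ValueError("more TFs requested than genes simulated")
    rng = _rng(cfg, 5)
    gene_ids = list(genes["gene_id"])
    tf_ids = gene_ids[: cfg.n_tfs]
    pwms = {}
    for tf in tf_ids:
        cons = rng.integers(0, 4, size=cfg.motif_length)
        mat = np.full((cfg.motif_length, 4), 0.05)
        mat[np.arange(cfg.motif_length), cons] = 0.85
        pwms[tf] = PWM(tf, mat)
    promoters = {
        g: "".join(BASES[b] for b in rng.integers(0, 4, size=cfg.promoter_length))
        for g in gene_ids
    }
    planted = {}
    n_targets = max(1, int(round(0.2 * len(gene_ids))))
    for tf in tf_ids:
        targets = rng.choice(len(gene_ids), size=n_targets, replace=False)
        planted[tf] = {}
        cons = pwms[tf].consensus
        for gi in targets:
            g = gene_ids[gi]
            pos = int(rng.integers(0, cfg.promoter_length - cfg.motif_length + 1))
            seq = promoters[g]
            promoters[g] = seq[:pos] + cons + seq[pos + cfg.motif_length:]
            planted[tf][g] = pos + 1  # 1-based
    return pwms, promoters, planted


def simulate_all(cfg: SimConfig) -> dict:
    """Run every generator and return the full input bundle as a dict."""
    mmap = simulate_marker_map(cfg)
    G = simulate_genotypes(mmap, cfg)
    truth, responses = simulate_traits(G, cfg)
    genes = simulate_gene_annotation(mmap, cfg)
    pwms, promoters, planted = simulate_motifs_and_promoters(genes, cfg)
    return {
        "config": cfg,
        "marker_map": mmap,
        "genotypes": G,
        "truth": truth,
        "responses": responses,
        "genes": genes,
        "pwms": pwms,
        "promoters": promoters,
        "planted": planted,
        "tf_list": list(pwms),
    }
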