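"""Synthetic inbred panels, gene models and trial phenotypes with ground truth.

The generator emulates the statistical structure the heterosis analysis
assumes: ~24 fully homozygous inbreds in three heterotic groups whose
allele frequencies diverge under a Balding-Nichols model; non-overlapping
gene models with promoter-compatible upstream space, exons, UTRs and a
stop codon; and multi-location replicated grain-yield plots generated
from a dominance genetic architecture in which causal loci sit (by
default entirely) inside PEUS regions. Because heterozygosity at
dominance loci is the generative source of heterosis, the headline
property of the analysis — the heterozygous PEUS SNP count predicting
MPH better than genome-wide GD — is true by construction and can be used
for recovery testing.

Random streams are split per component (annotation is deterministic;
genotypes / effects / noise get independent child seeds), so changing
the phenotype seed leaves the genotypes fixed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, PeusAnnotation, Transcript
from .genotype_io import GenotypeMatrix
from .scoring import CrossDesign, cross_id

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the trial layout the analysis targets: 24 inbreds in
    three heterotic groups (8 Reid incl. the 5 testers, 13 nonReid, 3
    Suwan1), a 19 line x 5 tester factorial (95 crosses), and grain yield
    from 3 locations x 3 replications. Genome size is desk-scale; effect
    and noise magnitudes are chosen to give maize-like mid-parent
    heterosis of a few tens of percent.
    """

    seed: int = 0
    n_groups: int = 3
    group_names: tuple[str, ...] = ("Reid", "nonReid", "Suwan1")
    group_sizes: tuple[int, ...] = (8, 13, 3)
    n_testers: int = 5
    fst: float = 0.15
    n_chromosomes: int = 2
    chrom_length: int = 1_500_000
    n_genes: int = 150
    n_snps: int = 3000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    causal_fraction_of_peus: float = 0.30
    dominance_effect_mean: float = 0.20  # t/ha per heterozygous causal locus
    additive_effect_mean: float = 0.04   # t/ha scale of additive deviations
    off_peus_effect_fraction: float = 0.0
    n_locations: int = 3
    n_reps: int = 3
    location_effect_sd: float = 1.0      # t/ha
    rep_effect_sd: float = 0.2           # t/ha, replications within location
    gxe_sd: float = 0.3                  # t/ha, entry x location
    plot_noise_sd: float = 0.8           # t/ha
    grand_mean_gy: float = 6.0           # t/ha

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if len(self.group_sizes) != self.n_groups or len(self.group_names) != self.n_groups:
            raise ValueError("group_names/group_sizes must match n_groups")
        if self.n_testers > self.group_sizes[0]:
            raise ValueError("testers are drawn from the first group; too few members")
        for sd in (self.location_effect_sd, self.rep_effect_sd, self.gxe_sd, self.plot_noise_sd):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        for frac in (self.causal_fraction_of_peus, self.off_peus_effect_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class TruthBundle:
    """Ground truth underlying one simulated experiment."""

    causal_sites: np.ndarray          # site indices into the genotype matrix
    causal_in_peus: np.ndarray        # bool per causal site
    additive: np.ndarray              # a per causal site
    dominance: np.ndarray             # d per causal site
    group_freqs: pd.DataFrame | None  # per-locus allele frequencies per group
    genetic_values: dict[str, float]  # entry id -> genetic value (t/ha)

    def to_json(self, path: str) -> None:
        payload = {
            "causal_sites": self.causal_sites.tolist(),
            "causal_in_peus": self.causal_in_peus.tolist(),
            "additive": self.additive.tolist(),
            "dominance": self.dominance.tolist(),
            "genetic_values": self.genetic_values,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def panel(cfg: SimulationConfig) -> tuple[list[str], dict[str, str], dict[str, str]]:
    """(samples, groups, roles) for the inbred panel.

    Testers are the first ``n_testers`` members of the first heterotic
    group; every other inbred is a line.
    """
    samples: list[str] = []
    groups: dict[str, str] = {}
    roles: dict[str, str] = {}
    line_no = 0
    for gname, gsize in zip(cfg.group_names, cfg.group_sizes):
        for k in range(gsize):
            if gname == cfg.group_names[0] and k < cfg.n_testers:
                s = f"T{k + 1}"
                roles[s] = "tester"
            else:
                line_no += 1
                s = f"L{line_no:02d}"
                roles[s] = "line"
            samples.append(s)
            groups[s] = gname
    return samples, groups, roles


def make_design(cfg: SimulationConfig) -> CrossDesign:
    """Full line x tester factorial over the panel (19 x 5 = 95 by default)."""
    samples, groups, roles = panel(cfg)
    lines = [s for s in samples if roles[s] == "line"]
    testers = [s for s in samples if roles[s] == "tester"]
    crosses = [(f, m) for f in lines for m in testers]
    return CrossDesign(crosses=crosses, roles=roles, groups=groups)


# ---------------------------------------------------------------------------
# gene models

_UTR5, _UTR3, _INTRON = 150, 210, 120
_CDS_SINGLE = 900
_CDS_SPLIT = (450, 450)


def simulate_annotation(cfg: SimulationConfig) -> list[GeneModel]:
    """Deterministic non-overlapping gene models on alternating strands.

    Genes are laid out in equal slots per chromosome, each with >= 1 kb of
    intergenic space on both sides so promoters never overlap a
    neighbouring gene. Every third gene has its CDS split across two exons
    by an intron; layouts are mirrored on the minus strand.
    """
    per_chrom = cfg.n_genes // cfg.n_chromosomes + (cfg.n_genes % cfg.n_chromosomes > 0)
    slot = cfg.chrom_length // per_chrom
    span = _UTR5 + _CDS_SINGLE + _INTRON + _UTR3
    if slot < span + 2 * 1100:
        raise ValueError(
            f"infeasible packing: {cfg.n_genes} genes of span ~{span} bp (+1 kb "
            f"margins) do not fit {cfg.n_chromosomes} x {cfg.chrom_length} bp"
        )
    genes: list[GeneModel] = []
    gi = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        for s in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            g = s * slot + 1100 + 1  # 1-based gene start, promoter room upstream
            strand = "+" if gi % 2 == 0 else "-"
            split = gi % 3 == 0
            genes.append(_make_gene(f"gene{gi + 1:04d}", chrom, strand, g, split))
            gi += 1
    return genes


def _make_gene(gene_id: str, chrom: str, strand: str, g: int, split: bool) -> GeneModel:
    if strand == "+":
        left_utr, right_utr = _UTR5, _UTR3
    else:
        left_utr, right_utr = _UTR3, _UTR5
    if not split:
        cds = [(g + left_utr, g + left_utr + _CDS_SINGLE - 1)]
        exons = [(g, cds[0][1] + right_utr)]
    else:
        c1 = (g + left_utr, g + left_utr + _CDS_SPLIT[0] - 1)
        c2_start = c1[1] + _INTRON + 1
        c2 = (c2_start, c2_start + _CDS_SPLIT[1] - 1)
        cds = [c1, c2]
        exons = [(g, c1[1]), (c2[0], c2[1] + right_utr)]
    end = exons[-1][1]
    if strand == "+":
        utr5 = [(g, g + left_utr - 1)]
        utr3 = [(end - right_utr + 1, end)]
    else:
        utr3 = [(g, g + left_utr - 1)]
        utr5 = [(end - right_utr + 1, end)]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=[Transcript(exons=exons, cds=cds, utr5=utr5, utr3=utr3)],
    )


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        tr_all = [iv for t in gene.transcripts for iv in t.exons]
        g_start = min(a for a, _ in tr_all)
        g_end = max(b for _, b in tr_all)
        base = f"{gene.chrom}\theteropeus\t"
        tail = f"\t.\t{gene.strand}\t"
        lines.append(f"{base}gene\t{g_start}\t{g_end}{tail}.\tID={gene.gene_id}")
        for ti, t in enumerate(gene.transcripts, start=1):
            tid = f"{gene.gene_id}.t{ti}"
            t_start = min(a for a, _ in t.exons)
            t_end = max(b for _, b in t.exons)
            lines.append(f"{base}mRNA\t{t_start}\t{t_end}{tail}.\tID={tid};Parent={gene.gene_id}")
            for a, b in t.exons:
                lines.append(f"{base}exon\t{a}\t{b}{tail}.\tParent={tid}")
            phase = 0
            cds_order = sorted(t.cds, reverse=(gene.strand == "-"))
            for a, b in cds_order:
                lines.append(f"{base}CDS\t{a}\t{b}{tail}{phase}\tParent={tid}")
                phase = (3 - ((b - a + 1 - phase) % 3)) % 3
            for a, b in t.utr5:
                lines.append(f"{base}five_prime_UTR\t{a}\t{b}{tail}.\tParent={tid}")
            for a, b in t.utr3:
                lines.append(f"{base}three_prime_UTR\t{a}\t{b}{tail}.\tParent={tid}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotypes

def simulate_inbreds(cfg: SimulationConfig, seed: int | None = None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Fully homozygous inbred panel under Balding-Nichols divergence.

    Per locus, an ancestral frequency p is drawn uniformly from
    ``ancestral_freq_range``; each heterotic group's frequency comes from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst``; each inbred is dosage
    2 with its group's frequency, else 0 (no residual heterozygosity).
    All depth/GQ/QUAL values pass the default quality filters.

    Returns the matrix and the per-group allele-frequency table.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([int(seed), 1])
    samples, groups, _ = panel(cfg)
    n_samples = len(samples)

    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    chroms, pos = [], []
    for c, m in enumerate(per_chrom):
        p = np.sort(rng.choice(cfg.chrom_length, size=int(m), replace=False)) + 1
        chroms.extend([f"chr{c + 1}"] * int(m))
        pos.extend(p.tolist())
    n_sites = len(pos)

    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_sites)
    f = cfg.fst
    freq = {}
    for gname in cfg.group_names:
        freq[gname] = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
    dosage = np.empty((n_samples, n_sites), dtype=np.int8)
    for i, s in enumerate(samples):
        dosage[i] = 2 * (rng.random(n_sites) < freq[groups[s]]).astype(np.int8)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "qual": np.round(rng.uniform(100, 1000, size=n_sites), 2),
        }
    )
    depth = (rng.poisson(5, size=(n_samples, n_sites)) + 3).astype(np.int32)
    gq = rng.integers(30, 100, size=(n_samples, n_sites), dtype=np.int32)
    gm = GenotypeMatrix(samples, sites, dosage, depth, gq)
    freq_df = pd.DataFrame(freq)
    return gm, freq_df


# ---------------------------------------------------------------------------
# phenotypes

def _entry_dosage_het(
    gm: GenotypeMatrix, design: CrossDesign, causal: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per entry: (mean dosage, heterozygosity flags) at the causal loci."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in design.parents:
        d = gm.dosage[gm.sample_index(s), causal].astype(float)
        out[s] = (d, d == 1)
    for female, male in design.crosses:
        df = gm.dosage[gm.sample_index(female), causal].astype(float)
        dm = gm.dosage[gm.sample_index(male), causal].astype(float)
        out[cross_id(female, male)] = ((df + dm) / 2.0, df != dm)
    return out


def simulate_phenotypes(
    gm: GenotypeMatrix,
    ann: PeusAnnotation,
    design: CrossDesign,
    cfg: SimulationConfig,
    seed: int | None = None,
    group_freqs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Plot-level grain yield from a dominance architecture at causal loci.

    The genetic value of an entry is sum over causal loci of
    a*(dosage - 1) + d*[heterozygous]; an F1's dosage at a locus is the
    mean of its parents' (heterozygous iff they differ). A plot's yield is
    grand mean + location + rep(location) + genetic value + GxE + noise,
    truncated at zero (logged if it occurs). Parents are phenotyped in
    every location/replication exactly like the F1s.

    Causal loci are drawn from PEUS sites, except for a fraction
    ``off_peus_effect_fraction`` drawn from non-PEUS sites. Additive
    deviations a ~ Normal(0, additive_effect_mean); dominance effects
    d ~ Exponential(dominance_effect_mean), strictly positive, which is
    what makes heterozygosity yield-increasing.
    """
    seed = cfg.seed if seed is None else seed
    eff_rng = np.random.default_rng([int(seed), 2])
    noise_rng = np.random.default_rng([int(seed), 3])

    peus_idx = np.flatnonzero(ann.is_peus)
    off_idx = np.flatnonzero(~ann.is_peus)
    n_causal = max(1, int(round(cfg.causal_fraction_of_peus * len(peus_idx))))
    n_off = int(round(cfg.off_peus_effect_fraction * n_causal))
    n_on = n_causal - n_off
    if n_on > len(peus_idx) or n_off > len(off_idx):
        raise ValueError("not enough sites to place causal loci")
    causal = np.concatenate(
        [
            eff_rng.choice(peus_idx, size=n_on, replace=False) if n_on else np.empty(0, int),
            eff_rng.choice(off_idx, size=n_off, replace=False) if n_off else np.empty(0, int),
        ]
    ).astype(int)
    in_peus = np.concatenate([np.ones(n_on, bool), np.zeros(n_off, bool)])
    a = eff_rng.normal(0.0, cfg.additive_effect_mean, size=n_causal)
    d = eff_rng.exponential(cfg.dominance_effect_mean, size=n_causal)

    entries = _entry_dosage_het(gm, design, causal)
    gvalues = {
        e: float(np.sum(a * (dos - 1.0)) + np.sum(d[het]))
        for e, (dos, het) in entries.items()
    }

    locations = [f"Loc{i + 1}" for i in range(cfg.n_locations)]
    loc_eff = noise_rng.normal(0.0, cfg.location_effect_sd, size=cfg.n_locations)
    rep_eff = noise_rng.normal(0.0, cfg.rep_effect_sd, size=(cfg.n_locations, cfg.n_reps))
    entry_ids = list(entries)
    gxe = noise_rng.normal(0.0, cfg.gxe_sd, size=(len(entry_ids), cfg.n_locations))

    rows = []
    n_truncated = 0
    for ei, entry in enumerate(entry_ids):
        etype = "parent" if entry in design.roles else "F1"
        base = cfg.grand_mean_gy + gvalues[entry]
        eps = noise_rng.normal(0.0, cfg.plot_noise_sd, size=(cfg.n_locations, cfg.n_reps))
        for l, loc in enumerate(locations):
            for k in range(cfg.n_reps):
                gy = base + loc_eff[l] + rep_eff[l, k] + gxe[ei, l] + eps[l, k]
                if gy < 0:
                    gy = 0.0
                    n_truncated += 1
                rows.append(
                    {
                        "entry_id": entry,
                        "entry_type": etype,
                        "location": loc,
                        "replication": k + 1,
                        "gy": gy,
                    }
                )
    if n_truncated:
        logger.warning("simulate_phenotypes: %d plots truncated at 0 yield", n_truncated)
    truth = TruthBundle(
        causal_sites=causal,
        causal_in_peus=in_peus,
        additive=a,
        dominance=d,
        group_freqs=group_freqs,
        genetic_values=gvalues,
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# whole experiment

@dataclass
class SimBundle:
    gm: GenotypeMatrix
    genes: list[GeneModel]
    design: CrossDesign
    plots: pd.DataFrame
    truth: TruthBundle
    annotation: PeusAnnotation
    paths: dict[str, str] = field(default_factory=dict)


def full_experiment(
    cfg: SimulationConfig, seed: int | None = None, outdir: str | None = None
) -> SimBundle:
    """Simulate everything the pipeline needs, optionally writing files.

    With ``outdir`` set, writes genotypes.vcf, genes.gff3, design.csv,
    plots.csv and truth.json — sufficient to run the full pipeline with
    no other input.
    """
    from .annotation import annotate_matrix, build_region_index
    from .genotype_io import write_vcf

    seed = cfg.seed if seed is None else seed
    genes = simulate_annotation(cfg)
    gm, freqs = simulate_inbreds(cfg, seed)
    design = make_design(cfg)
    idx = build_region_index(genes)
    ann = annotate_matrix(gm, idx)
    plots, truth = simulate_phenotypes(gm, ann, design, cfg, seed, group_freqs=freqs)

    paths: dict[str, str] = {}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": str(out / "genotypes.vcf"),
            "gff3": str(out / "genes.gff3"),
            "design": str(out / "design.csv"),
            "plots": str(out / "plots.csv"),
            "truth": str(out / "truth.json"),
        }
        write_vcf(gm, paths["vcf"])
        write_gff3(genes, paths["gff3"])
        design.to_frame().to_csv(paths["design"], index=False)
        plots.to_csv(paths["plots"], index=False)
        truth.to_json(paths["truth"])
    return SimBundle(gm=gm, genes=genes, design=design, plots=plots, truth=truth,
                     annotation=ann, paths=paths)


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. parsed YAML)."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    for key in ("group_names", "group_sizes", "ancestral_freq_range"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimulationConfig(**data)
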