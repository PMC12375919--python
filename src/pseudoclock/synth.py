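"""Synthetic neutrally-evolving coding sequences with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
set of reference CDSs (ATG start, sense interior codons, terminal stop,
optional GT/AG introns) evolves without selection for ``g_true``
generations. Point substitutions arrive as a Poisson process with
per-site rate mu and a transition/transversion bias kappa (a K2P-like
model — the two parameters the rate model actually uses); small indels
arrive at ``indel_rate`` per site with geometric(0.5) lengths truncated
at 10 bp, so roughly six in seven indels shift the reading frame; splice
dinucleotides mutate at the same per-site point rate. Read support at
LoF sites is drawn binomially around the genotype truth.

Every LoF event introduced is recorded in a truth table and then verified
against the final sequence by local codon checks (an event destroyed by a
later mutation, or a premature stop left out of frame by an indel, no
longer exists in the emitted data and is dropped). The verification is
deliberately local — it never re-runs the screening module — so the
screen round-trip remains an independent check.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from pseudoclock.gene_models import (
    GeneModel,
    GeneSet,
    ReadSupportRecord,
    write_gene_models,
    write_read_support,
    write_sequences,
)

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
SENSE = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the amblyopsid vision-gene setting: 88 genes of about
    1 kb with a handful of introns each, mu = 1e-8 per site per
    generation, kappa = 1.76, and 2.5e5 generations of relaxed selection.
    The indel rate (7e-10 per site per generation) is set so the
    frameshift-to-premature-stop ratio lands near the observed 46/30.
    """

    n_genes: int = 88
    gene_length: int = 999  # bp, multiple of 3
    n_introns: int = 5
    mu: float = 1e-8
    kappa: float = 1.76
    indel_rate: float = 7e-10
    indel_geom_p: float = 0.5
    indel_max_len: int = 10
    g_true: float = 2.5e5
    coverage_mean: float = 20.0
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_length < 6 or self.gene_length % 3 != 0:
            raise ValueError("gene_length must be >= 6 and a multiple of 3")
        for name in ("mu", "kappa", "indel_rate", "g_true", "coverage_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def _rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def _mutate_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    """Draw a substitute base with transition probability kappa/(kappa+2)."""
    if rng.random() < kappa / (kappa + 2.0):
        return TRANSITION[base]
    return TRANSVERSIONS[base][rng.integers(2)]


def make_gene_set(config: SimConfig) -> tuple[GeneSet, dict[str, str]]:
    """Random reference gene models and CDS sequences.

    Each CDS starts with ATG, ends with a random stop codon and contains
    only sense codons in between; introns (GT/AG) split the CDS-local
    coordinates at random codon boundaries.
    """
    rng = _rng(config)
    models = []
    sequences: dict[str, str] = {}
    n_codons = config.gene_length // 3
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:03d}"
        interior = rng.choice(SENSE, size=n_codons - 2)
        seq = "ATG" + "".join(interior) + STOPS[rng.integers(3)]
        n_introns = min(config.n_introns, n_codons - 2)
        if n_introns > 0:
            # split points at distinct interior codon boundaries
            cuts = 3 * (
                1 + rng.choice(np.arange(1, n_codons - 1), n_introns, replace=False)
            )
            cuts.sort()
            bounds = []
            prev = 0
            for cut in [*cuts, config.gene_length]:
                bounds.append((prev + 1, int(cut)))
                prev = int(cut)
        else:
            bounds = [(1, config.gene_length)]
        models.append(
            GeneModel(gene_id=gene_id, exon_bounds=tuple(bounds))
        )
        sequences[gene_id] = seq
    return GeneSet(models=tuple(models)), sequences


@dataclass
class EvolvedGene:
    """One gene after neutral evolution: a pairwise alignment plus introns."""

    gene_id: str
    reference_aln: str
    observed_aln: str
    observed_introns: list[tuple[str, str]]


def _apply_substitutions(seq, model, config, rng, events):
    """Point substitutions with candidate LoF events recorded."""
    L = len(seq)
    n_sub = rng.poisson(config.mu * L * config.g_true)
    seq = list(seq)
    for _ in range(n_sub):
        pos = int(rng.integers(L))  # 0-based
        old = seq[pos]
        seq[pos] = _mutate_base(old, config.kappa, rng)
        codon_start = 3 * (pos // 3)
        codon = "".join(seq[codon_start : codon_start + 3])
        if codon_start == 0:
            if codon != "ATG":
                events.append((model.gene_id, "start_loss", 1, "substitution"))
        elif codon_start == L - 3:
            if codon not in STOPS:
                events.append(
                    (model.gene_id, "stop_loss", L - 2, "substitution")
                )
        elif codon in STOPS:
            events.append(
                (model.gene_id, "premature_stop", codon_start + 1, codon)
            )
    return "".join(seq)


def _apply_indels(ref_aln, obs_aln, model, config, rng, events):
    """Insertions/deletions on the alignment, never merging gap runs."""
    columns = [list(t) for t in zip(ref_aln, obs_aln)]
    L = len(ref_aln)
    n_indel = rng.poisson(config.indel_rate * L * config.g_true)
    geom = np.minimum(
        rng.geometric(config.indel_geom_p, size=n_indel), config.indel_max_len
    )
    for length in geom:
        length = int(length)
        is_deletion = rng.random() < 0.5
        placed = False
        for _ in range(30):  # rejection-sample a clean placement
            if is_deletion:
                start = int(rng.integers(len(columns) - length + 1))
                window = columns[max(start - 1, 0) : start + length + 1]
                if any(c[0] == "-" or c[1] == "-" for c in window):
                    continue  # would merge with an existing gap run
                for c in columns[start : start + length]:
                    c[1] = "-"
                ref_pos = sum(
                    1 for c in columns[: start + 1] if c[0] != "-"
                )
                detail = f"deletion of {length} bp"
            else:
                at = int(rng.integers(len(columns) + 1))
                neighbours = columns[max(at - 1, 0) : at + 1]
                if any(c[0] == "-" or c[1] == "-" for c in neighbours):
                    continue  # would merge with or split an existing run
                new = [
                    ["-", BASES[rng.integers(4)]] for _ in range(length)
                ]
                columns[at:at] = new
                ref_pos = sum(1 for c in columns[:at] if c[0] != "-") + 1
                detail = f"insertion of {length} bp"
            placed = True
            break
        if placed and length % 3 != 0:
            events.append((model.gene_id, "frameshift", ref_pos, detail))
    ref_aln = "".join(c[0] for c in columns)
    obs_aln = "".join(c[1] for c in columns)
    return ref_aln, obs_aln


def _evolve_introns(model, config, rng, events):
    """Mutate splice dinucleotides at the point rate; record disruptions."""
    p_site = -np.expm1(-config.mu * config.g_true)
    observed = []
    for idx in range(model.intron_count):
        donor = list(model.donors[idx])
        acceptor = list(model.acceptors[idx])
        for duo, name in ((donor, "donor"), (acceptor, "acceptor")):
            for j in range(2):
                if rng.random() < p_site:
                    duo[j] = _mutate_base(duo[j], config.kappa, rng)
        donor_s, acceptor_s = "".join(donor), "".join(acceptor)
        if donor_s != "GT":
            events.append(
                (model.gene_id, "splice_site", idx + 1, f"donor GT->{donor_s}")
            )
        if acceptor_s != "AG":
            events.append(
                (
                    model.gene_id,
                    "splice_site",
                    idx + 1,
                    f"acceptor AG->{acceptor_s}",
                )
            )
        observed.append((donor_s, acceptor_s))
    return observed


def _verify_events(events, ref_aln, obs_aln, gene_id):
    """Keep only events still present in the final sequence.

    Local codon checks against the alignment: a start/stop-loss must
    still read as a non-ATG/non-stop codon; a premature stop must still
    be an intact in-frame stop — in frame meaning the net indel offset
    upstream of its codon is a multiple of 3 and no gap column interrupts
    the codon itself.
    """
    by_pos: dict[int, str] = {}  # ref position -> observed char
    inserted_before: dict[int, int] = {}  # ref position -> insertions 5' of it
    deleted_before: dict[int, int] = {}
    pos = 0
    n_ins = 0
    n_del = 0
    for r, o in zip(ref_aln, obs_aln):
        if r == "-":
            n_ins += 1
            continue
        pos += 1
        by_pos[pos] = o
        inserted_before[pos] = n_ins
        deleted_before[pos] = n_del
        if o == "-":
            n_del += 1
    L = pos
    kept = []
    for gid, kind, position, detail in events:
        if gid != gene_id:
            continue
        if kind == "frameshift" or kind == "splice_site":
            kept.append((gid, kind, position, detail))
        elif kind == "start_loss":
            codon = "".join(
                by_pos[p] for p in (1, 2, 3) if by_pos.get(p, "-") != "-"
            )
            if codon != "ATG":
                kept.append((gid, kind, position, detail))
        elif kind == "stop_loss":
            codon = "".join(
                by_pos[p]
                for p in (L - 2, L - 1, L)
                if by_pos.get(p, "-") != "-"
            )
            if codon not in STOPS:
                kept.append((gid, kind, position, detail))
        elif kind == "premature_stop":
            codon = "".join(
                by_pos.get(p, "-") for p in range(position, position + 3)
            )
            offset = inserted_before[position] - deleted_before[position]
            intact = (
                codon in STOPS
                and offset % 3 == 0
                and inserted_before[min(position + 2, L)]
                == inserted_before[position]
            )
            if intact:
                kept.append((gid, kind, position, detail))
    return kept


def evolve_neutral(
    gene_set: GeneSet,
    references: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, EvolvedGene], pd.DataFrame]:
    """Evolve every reference CDS neutrally for ``g_true`` generations.

    Returns the evolved alignments (with observed splice dinucleotides)
    and the verified truth table of introduced LoF events
    (columns: gene_id, kind, position, detail).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    evolved: dict[str, EvolvedGene] = {}
    truth_rows = []
    for model in gene_set:
        ref = references[model.gene_id]
        events: list[tuple] = []
        mutated = _apply_substitutions(ref, model, config, rng, events)
        ref_aln, obs_aln = _apply_indels(ref, mutated, model, config, rng, events)
        observed_introns = _evolve_introns(model, config, rng, events)
        kept = _verify_events(events, ref_aln, obs_aln, model.gene_id)
        truth_rows.extend(
            {"gene_id": g, "kind": k, "position": p, "detail": d}
            for g, k, p, d in kept
        )
        evolved[model.gene_id] = EvolvedGene(
            gene_id=model.gene_id,
            reference_aln=ref_aln,
            observed_aln=obs_aln,
            observed_introns=observed_introns,
        )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "kind", "position", "detail"]
    )
    return evolved, truth


def make_read_support(
    genotype_truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadSupportRecord]:
    """Binomially sampled read support at LoF sites.

    ``genotype_truth`` needs columns gene_id, position, genotype
    (hom_lof / hom_ref / het). Depth is Poisson(coverage_mean); het sites
    split reads Binomial(n, 1/2); homozygous sites put all reads on one
    allele apart from an optional per-read error rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    records = []
    for row in genotype_truth.itertuples():
        n = int(rng.poisson(config.coverage_mean))
        err = config.base_error_rate
        if row.genotype == "het":
            k_lof = int(rng.binomial(n, 0.5)) if n else 0
        elif row.genotype == "hom_lof":
            k_lof = n - (int(rng.binomial(n, err)) if err and n else 0)
        elif row.genotype == "hom_ref":
            k_lof = int(rng.binomial(n, err)) if err and n else 0
        else:
            raise ValueError(f"unknown genotype truth {row.genotype!r}")
        records.append(
            ReadSupportRecord(
                gene_id=row.gene_id,
                position=int(row.position),
                reads_supporting_lof=k_lof,
                reads_opposing_lof=n - k_lof,
            )
        )
    return records


def simulate_dataset(config: SimConfig) -> dict:
    """Full fixture: gene set, references, evolved sequences, truth tables.

    Genotype truth assigns every truth LoF site homozygous-LoF (fixed
    under neutrality) and adds one heterozygous and one homozygous-
    reference control site per gene for the genotyping stage.
    """
    gene_set, references = make_gene_set(config)
    evolved, truth = evolve_neutral(
        gene_set, references, config, np.random.default_rng(config.seed + 1)
    )
    rng = np.random.default_rng(config.seed + 2)
    geno_rows = [
        {"gene_id": r.gene_id, "position": r.position, "genotype": "hom_lof"}
        for r in truth.itertuples()
    ]
    for model in gene_set:
        site_het = int(rng.integers(1, model.cds_length + 1))
        site_ref = int(rng.integers(1, model.cds_length + 1))
        geno_rows.append(
            {"gene_id": model.gene_id, "position": site_het, "genotype": "het"}
        )
        geno_rows.append(
            {"gene_id": model.gene_id, "position": site_ref, "genotype": "hom_ref"}
        )
    genotype_truth = pd.DataFrame(
        geno_rows, columns=["gene_id", "position", "genotype"]
    )
    read_support = make_read_support(genotype_truth, config, rng)
    return {
        "config": config,
        "gene_set": gene_set,
        "references": references,
        "evolved": evolved,
        "truth": truth,
        "genotype_truth": genotype_truth,
        "read_support": read_support,
    }


def write_fixture(dataset: dict, out_dir: str | Path) -> None:
    """Write a complete fixture directory in the interchange dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_gene_models(dataset["gene_set"], out_dir / "gene_models.tsv")
    write_sequences(
        {"reference": dataset["references"]}, out_dir / "reference.fasta"
    )
    observed = {
        "evolved": {
            gid: ev.observed_aln for gid, ev in dataset["evolved"].items()
        }
    }
    write_sequences(observed, out_dir / "observed.fasta")
    dataset["truth"].to_csv(out_dir / "truth_lof.tsv", sep="\t", index=False)
    dataset["genotype_truth"].to_csv(
        out_dir / "truth_genotypes.tsv", sep="\t", index=False
    )
    write_read_support(dataset["read_support"], out_dir / "read_support.tsv")
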