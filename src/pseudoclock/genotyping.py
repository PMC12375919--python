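"""Genotype calls at LoF sites from read-support counts.

At a site where some reads support the LoF allele and some the reference
allele, the genotype is decided by a cumulative binomial test under the
null of a heterozygote (each read equally likely to come from either
allele). With n total reads and k the minor count, p = P(X <= k) for
X ~ Binomial(n, 1/2); p < alpha rejects heterozygosity and the site is
called homozygous for the majority allele, otherwise heterozygous.

The test is one-sided on the minor allele: p is the probability that the
allele supported by the minimum read count is a true allele. A two-sided
variant (doubling p, capped at 1) is available behind ``two_sided=True``
but off by default. Ties (equal counts) have p >= 0.5 and are therefore
always heterozygous. For fewer than 5 reads even k = 0 gives
p = 0.5**n >= 0.0625 > 0.05, so no homozygous call is possible at the
default alpha; such calls carry a low-depth flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binom

from pseudoclock.gene_models import ReadSupportRecord

MIN_DEPTH_FOR_HOM = 5  # below this, 0.5**n > 0.05: hom calls unreachable


@dataclass(frozen=True)
class GenotypeCall:
    gene_id: str
    position: int
    genotype: str  # hom_lof | hom_ref | het
    p_value: float
    n_reads: int
    low_depth: bool = False


class NoCallError(ValueError):
    """Zero reads on both alleles: the site cannot be genotyped."""


def call_genotype(
    reads_lof: int,
    reads_ref: int,
    alpha: float = 0.05,
    *,
    two_sided: bool = False,
    gene_id: str = ".",
    position: int = 0,
) -> GenotypeCall:
    """Call hom_lof / hom_ref / het from read counts.

    Raises :class:`NoCallError` when both counts are zero.
    """
    if reads_lof < 0 or reads_ref < 0:
        raise ValueError("read counts must be non-negative")
    n = reads_lof + reads_ref
    if n == 0:
        raise NoCallError(f"{gene_id}:{position}: zero reads on both alleles")
    k = min(reads_lof, reads_ref)
    p = float(binom.cdf(k, n, 0.5))
    if two_sided:
        p = min(1.0, 2.0 * p)
    if p < alpha:
        genotype = "hom_lof" if reads_lof > reads_ref else "hom_ref"
    else:
        genotype = "het"
    return GenotypeCall(
        gene_id=gene_id,
        position=position,
        genotype=genotype,
        p_value=p,
        n_reads=n,
        low_depth=n < MIN_DEPTH_FOR_HOM,
    )


def genotype_table(
    records: Sequence[ReadSupportRecord],
    alpha: float = 0.05,
    *,
    two_sided: bool = False,
) -> tuple[pd.DataFrame, list[ReadSupportRecord]]:
    """Genotype every record; zero-depth records go to a no-call list.

    Returns ``(table, no_calls)`` where the table has one row per callable
    record in input order.
    """
    rows = []
    no_calls: list[ReadSupportRecord] = []
    for rec in records:
        if rec.total_reads == 0:
            no_calls.append(rec)
            continue
        call = call_genotype(
            rec.reads_supporting_lof,
            rec.reads_opposing_lof,
            alpha,
            two_sided=two_sided,
            gene_id=rec.gene_id,
            position=rec.position,
        )
        rows.append(
            {
                "gene_id": call.gene_id,
                "position": call.position,
                "genotype": call.genotype,
                "p_value": call.p_value,
                "n_reads": call.n_reads,
                "low_depth": call.low_depth,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "position", "genotype", "p_value", "n_reads", "low_depth"],
    )
    return table, no_calls


def genotype_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts of each genotype class in a genotype table."""
    counts = table["genotype"].value_counts().to_dict() if len(table) else {}
    return {g: int(counts.get(g, 0)) for g in ("hom_lof", "hom_ref", "het")}
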