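"""Loss-of-function screening of observed coding sequences.

A gene is screened by comparing its observed CDS (aligned to the reference
gene model's coordinate system) against the model. Five disruption classes
are recognised:

* ``premature_stop`` — an in-frame stop codon strictly before the terminal
  codon, with the reading frame tracked cumulatively through indels;
* ``frameshift`` — an insertion or deletion whose length mod 3 != 0;
* ``splice_site`` — an intron donor != GT or acceptor != AG;
* ``start_loss`` — the first codon is not ATG;
* ``stop_loss`` — the terminal codon is not one of TAA/TAG/TGA.

An ``N`` at any diagnostic position suppresses that call with a warning:
ambiguity is treated conservatively, as a human inspecting an alignment
would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pseudoclock.gene_models import GeneModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
GAP = "-"

LOF_KINDS = (
    "premature_stop",
    "frameshift",
    "splice_site",
    "start_loss",
    "stop_loss",
)


@dataclass(frozen=True)
class LoFMutation:
    """One typed loss-of-function disruption.

    ``position`` is the CDS-local 1-based coordinate of the first affected
    reference base; for ``splice_site`` it is the 1-based intron index, with
    the side (donor/acceptor) in ``detail``.
    """

    gene_id: str
    kind: str
    position: int
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LOF_KINDS:
            raise ValueError(f"unknown LoF kind {self.kind!r}")

    @property
    def descriptor(self) -> str:
        """Exact allele identity, used by the homoplasy screen."""
        return f"{self.gene_id}:{self.kind}@{self.position}:{self.detail}"


@dataclass(frozen=True)
class GeneStatus:
    gene_id: str
    status: str  # complete | incomplete | pseudogenized
    lof_mutations: tuple[LoFMutation, ...] = ()


class ScreenError(ValueError):
    """Observed sequence inconsistent with the declared gene model."""


def _align_columns(model: GeneModel, observed: str, reference: str | None):
    """Return per-column (ref_char, obs_char, ref_pos) for the alignment.

    ``ref_pos`` is the 1-based CDS-local coordinate of the reference base in
    that column, or the coordinate of the closest preceding reference base
    for insertion columns (where the reference carries a gap).
    """
    observed = observed.upper()
    if reference is None:
        if len(observed) != model.cds_length:
            raise ScreenError(
                f"{model.gene_id}: observed alignment length {len(observed)} "
                f"does not match declared CDS length {model.cds_length} "
                "(supply the gapped reference for alignments with insertions)"
            )
        reference = "N" * model.cds_length  # coordinates only; bases unused
    else:
        reference = reference.upper()
        if len(reference) != len(observed):
            raise ScreenError(
                f"{model.gene_id}: reference and observed alignment strings "
                f"differ in length ({len(reference)} vs {len(observed)})"
            )
        ungapped = len(reference) - reference.count(GAP)
        if ungapped != model.cds_length:
            raise ScreenError(
                f"{model.gene_id}: reference spans {ungapped} bp after gap "
                f"removal but the model declares {model.cds_length} bp"
            )
    columns = []
    ref_pos = 0
    for ref_char, obs_char in zip(reference, observed):
        if ref_char != GAP:
            ref_pos += 1
        columns.append((ref_char, obs_char, ref_pos))
    return columns


def _indel_runs(columns):
    """Yield (kind, ref_pos_start, length) for maximal gap runs."""
    runs = []
    current = None  # (kind, ref_pos, length)
    for ref_char, obs_char, ref_pos in columns:
        if obs_char == GAP and ref_char != GAP:
            kind = "deletion"
        elif ref_char == GAP and obs_char != GAP:
            kind = "insertion"
        else:
            kind = None
        if kind is None:
            if current:
                runs.append(current)
                current = None
        elif current and current[0] == kind:
            current = (kind, current[1], current[2] + 1)
        else:
            if current:
                runs.append(current)
            start = ref_pos if kind == "deletion" else ref_pos + 1
            current = (kind, start, 1)
    if current:
        runs.append(current)
    return runs


def _suppress(gene_id: str, what: str) -> None:
    warnings.warn(
        f"{gene_id}: ambiguous base (N) at {what}; call suppressed",
        stacklevel=3,
    )


def detect_lof(
    model: GeneModel,
    observed: str,
    reference: str | None = None,
    observed_introns: Sequence[tuple[str, str]] | None = None,
) -> list[LoFMutation]:
    """Detect all LoF mutations in ``observed`` relative to its gene model.

    Parameters
    ----------
    model
        Reference gene model supplying the coordinate system, CDS length
        and intron count.
    observed
        Observed CDS aligned to the reference: ``-`` marks deleted bases.
        Without ``reference`` the string must span exactly the reference
        coordinates (no insertions representable).
    reference
        Optional gapped reference string of the same pairwise alignment;
        required to represent insertions (reference gap columns).
    observed_introns
        Optional (donor, acceptor) 2-mers observed for each intron.

    Returns
    -------
    list of :class:`LoFMutation`, each disruption reported once. A
    premature stop created downstream of an uncompensated frameshift is
    still reported: mutation types are counted separately.
    """
    columns = _align_columns(model, observed, reference)
    mutations: list[LoFMutation] = []
    L = model.cds_length

    # --- indels -> frameshifts
    for kind, start, length in _indel_runs(columns):
        if length % 3 != 0:
            mutations.append(
                LoFMutation(
                    gene_id=model.gene_id,
                    kind="frameshift",
                    position=start,
                    detail=f"{kind} of {length} bp",
                )
            )

    # --- start codon (reference positions 1..3)
    start_chars = [c[1] for c in columns if c[0] != GAP and c[2] <= 3]
    if "N" in start_chars:
        _suppress(model.gene_id, "start codon")
    elif "".join(start_chars) != "ATG":
        observed_start = "".join(c for c in start_chars if c != GAP)
        mutations.append(
            LoFMutation(
                gene_id=model.gene_id,
                kind="start_loss",
                position=1,
                detail=f"start codon reads {observed_start or 'deleted'}",
            )
        )

    # --- terminal stop codon (reference positions L-2..L)
    stop_chars = [c[1] for c in columns if c[0] != GAP and c[2] > L - 3]
    if "N" in stop_chars:
        _suppress(model.gene_id, "terminal stop codon")
    elif "".join(stop_chars) not in STOP_CODONS:
        observed_stop = "".join(c for c in stop_chars if c != GAP)
        mutations.append(
            LoFMutation(
                gene_id=model.gene_id,
                kind="stop_loss",
                position=L - 2,
                detail=f"terminal codon reads {observed_stop or 'deleted'}",
            )
        )

    # --- premature stops, frame tracked through indels.
    # Reading the ungapped observed sequence codon-by-codon from its start
    # is exactly cumulative frame tracking: an uncompensated indel shifts
    # every downstream codon, compensating indels restore frame.
    obs_bases = [(c[1], c[2]) for c in columns if c[1] != GAP]
    for i in range(0, len(obs_bases) - 2, 3):
        codon = obs_bases[i][0] + obs_bases[i + 1][0] + obs_bases[i + 2][0]
        ref_pos = obs_bases[i][1]
        if ref_pos > L - 3:
            break  # at or beyond the terminal reference codon
        if "N" in codon:
            could_be_stop = any(
                all(codon[j] in ("N", stop[j]) for j in range(3))
                for stop in STOP_CODONS
            )
            if could_be_stop:
                _suppress(model.gene_id, f"codon at position {ref_pos}")
            continue
        if codon in STOP_CODONS:
            mutations.append(
                LoFMutation(
                    gene_id=model.gene_id,
                    kind="premature_stop",
                    position=ref_pos,
                    detail=f"{codon} at codon {(i // 3) + 1}",
                )
            )

    # --- splice sites
    if observed_introns is not None:
        if len(observed_introns) != model.intron_count:
            raise ScreenError(
                f"{model.gene_id}: {len(observed_introns)} observed introns "
                f"for a model with {model.intron_count}"
            )
        for idx, (donor, acceptor) in enumerate(observed_introns, start=1):
            donor = donor.upper()
            acceptor = acceptor.upper()
            if "N" in donor:
                _suppress(model.gene_id, f"intron {idx} donor")
            elif donor != "GT":
                mutations.append(
                    LoFMutation(
                        gene_id=model.gene_id,
                        kind="splice_site",
                        position=idx,
                        detail=f"donor GT->{donor}",
                    )
                )
            if "N" in acceptor:
                _suppress(model.gene_id, f"intron {idx} acceptor")
            elif acceptor != "AG":
                mutations.append(
                    LoFMutation(
                        gene_id=model.gene_id,
                        kind="splice_site",
                        position=idx,
                        detail=f"acceptor AG->{acceptor}",
                    )
                )

    return mutations


def classify_gene(
    mutations: Sequence[LoFMutation], truncated: bool, gene_id: str | None = None
) -> GeneStatus:
    """Three-way gene status: at least one LoF mutation means pseudogenized
    (taking precedence over truncation); a truncated sequence without LoF
    mutations is incomplete; otherwise the gene is complete.

    The truncation flag is supplied by the caller: whether an assembly
    recovered the full CDS cannot be decided from the CDS string alone.
    """
    if gene_id is None:
        gene_id = mutations[0].gene_id if mutations else "."
    if mutations:
        status = "pseudogenized"
    elif truncated:
        status = "incomplete"
    else:
        status = "complete"
    return GeneStatus(
        gene_id=gene_id, status=status, lof_mutations=tuple(mutations)
    )


def summarize_pseudogene_fractions(
    statuses_per_sample: Mapping[str, Sequence[GeneStatus]],
) -> pd.DataFrame:
    """Per-sample pseudogene fractions.

    Returns a table with columns ``sample``, ``n_examined``,
    ``n_pseudogenized``, ``fraction``; a sample with zero examined genes
    gets a NaN fraction and a warning rather than a silent 0.
    """
    rows = []
    for sample, statuses in statuses_per_sample.items():
        n_examined = len(statuses)
        n_pseudo = sum(1 for s in statuses if s.status == "pseudogenized")
        if n_examined == 0:
            warnings.warn(
                f"sample {sample}: zero genes examined; fraction undefined",
                stacklevel=2,
            )
            fraction = float("nan")
        else:
            fraction = n_pseudo / n_examined
        rows.append(
            {
                "sample": sample,
                "n_examined": n_examined,
                "n_pseudogenized": n_pseudo,
                "fraction": fraction,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "n_examined", "n_pseudogenized", "fraction"]
    )


def lof_table(
    mutations_per_sample: Mapping[str, Iterable[LoFMutation]],
) -> pd.DataFrame:
    """Flatten per-sample mutation lists into the interchange LoF table."""
    rows = [
        {
            "gene_id": m.gene_id,
            "sample_id": sample,
            "kind": m.kind,
            "position": m.position,
            "detail": m.detail,
        }
        for sample, muts in mutations_per_sample.items()
        for m in muts
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "kind", "position", "detail"]
    )
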