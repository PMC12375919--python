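"""The per-site loss-of-function mutation-rate model.

A point mutation can disable a gene in five ways, each with a per-site
probability:

* ``p_stop`` — the mutation turns a sense codon into a stop. Computed from
  the codon usage of the gene set and the transition/transversion ratio
  kappa: for each sense codon all nine single-nucleotide neighbours are
  enumerated, each weighted kappa (transition) or 1 (transversion), and
  p_stop is the usage-weighted fraction of weight landing on TAA/TAG/TGA.
* ``p_fs`` — the mutation is a frameshifting indel. Small indels are not
  modelled mechanistically; their rate is scaled off p_stop by the
  observed ratio of frameshift to premature-stop counts:
  p_fs = (N_FS / N_PSC) * p_stop.
* ``p_ss`` — the mutation hits a splice dinucleotide:
  4 * total_introns / sum_of_CDS_lengths (four GT/AG bases per intron).
* ``p_ml`` — start-codon loss: 3 * n_genes / sum_of_CDS_lengths.
* ``p_sl`` — stop-codon loss: 0.852 * p_ml, where 0.852 = 23/27 is the
  fraction of single-base stop-codon changes yielding a non-stop codon
  (4 of the 27 possible changes convert a stop into another stop).

The per-site per-generation LoF rate is their sum times the point
mutation rate mu: mu_lof = (p_fs + p_stop + p_ss + p_sl + p_ml) * mu.

The preset :data:`PRESET_COMPONENTS`\\ ``["paper2025"]`` ships the component
values published for the amblyopsid vision-gene set (0.046, 0.030, 0.021,
0.003, 0.003; multiplier 0.103), so the clock can run without the
underlying codon-usage table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

DEFAULT_KAPPA = 1.76
DEFAULT_MU = 1e-8
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
STOP_LOSS_FRACTION = round(23 / 27, 3)  # 0.852

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

PRESET_COMPONENTS: dict[str, dict[str, float]] = {
    # Published component values for the 88 amblyopsid vision genes
    # (p_fs, p_stop, p_ss, p_sl, p_ml summing to the 0.103 multiplier).
    "paper2025": {
        "p_fs": 0.046,
        "p_stop": 0.030,
        "p_ss": 0.021,
        "p_sl": 0.003,
        "p_ml": 0.003,
    },
}


def is_transition(a: str, b: str) -> bool:
    """True when a<->b is purine<->purine or pyrimidine<->pyrimidine."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


@dataclass(frozen=True)
class CodonUsage:
    """Relative frequency of each sense codon, normalised to sum 1.

    Stop codons are excluded: mutations within the terminal stop are the
    province of the stop-loss component, and counting them here would
    double-count.
    """

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = {}
        total = 0.0
        for codon, value in self.frequencies.items():
            codon = codon.upper()
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} not allowed in codon usage")
            if codon not in SENSE_CODONS:
                raise ValueError(f"invalid codon {codon!r}")
            if value < 0:
                raise ValueError(f"negative frequency for {codon}")
            freqs[codon] = float(value)
            total += value
        if total <= 0:
            raise ValueError("codon usage sums to zero")
        object.__setattr__(
            self, "frequencies", {c: v / total for c, v in freqs.items()}
        )

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "CodonUsage":
        """Tally sense-codon usage over ungapped CDS strings."""
        counts: dict[str, int] = {}
        for seq in sequences.values():
            seq = seq.upper().replace("-", "")
            for i in range(0, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS or any(b not in "ACGT" for b in codon):
                    continue
                counts[codon] = counts.get(codon, 0) + 1
        return cls(frequencies=counts)


@dataclass(frozen=True)
class MutationSpectrum:
    """Observed mutation-type counts and the ts/tv ratio kappa."""

    kappa: float = DEFAULT_KAPPA
    n_fs: int = 0
    n_psc: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_fs < 0 or self.n_psc < 0:
            raise ValueError("mutation counts must be non-negative")


def p_stop(usage: CodonUsage, kappa: float = DEFAULT_KAPPA) -> float:
    """Probability that a single-nucleotide change creates a stop codon.

    For each sense codon the nine single-base neighbours are enumerated;
    a change is weighted ``kappa`` if it is a transition and 1 if it is a
    transversion, and the usage-weighted fraction of weight landing on a
    stop codon is returned.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    total_weight = 0.0
    stop_weight = 0.0
    for codon, freq in usage.frequencies.items():
        if freq == 0:
            continue
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                w = kappa if is_transition(codon[pos], base) else 1.0
                neighbour = codon[:pos] + base + codon[pos + 1 :]
                total_weight += freq * w
                if neighbour in STOP_CODONS:
                    stop_weight += freq * w
    if total_weight == 0:
        raise ValueError("zero total mutational weight")
    return stop_weight / total_weight


def p_fs(spectrum: MutationSpectrum, p_stop_value: float) -> float:
    """Frameshift component: (N_FS / N_PSC) * p_stop."""
    if spectrum.n_psc == 0:
        raise ValueError("N_PSC = 0: frameshift/premature-stop ratio undefined")
    return (spectrum.n_fs / spectrum.n_psc) * p_stop_value


def p_ss(total_introns: int, sum_cds_lengths: int) -> float:
    """Splice-site component: 4 * introns / total CDS bp."""
    if sum_cds_lengths <= 0:
        raise ValueError("sum of CDS lengths must be positive")
    if total_introns < 0:
        raise ValueError("intron count must be non-negative")
    return 4.0 * total_introns / sum_cds_lengths


def p_ml(n_genes: int, sum_cds_lengths: int) -> float:
    """Start-loss component: 3 * n_genes / total CDS bp."""
    if sum_cds_lengths <= 0:
        raise ValueError("sum of CDS lengths must be positive")
    return 3.0 * n_genes / sum_cds_lengths


def p_sl(p_ml_value: float) -> float:
    """Stop-loss component: 0.852 * p_ml (0.852 = 23/27 to 3 decimals)."""
    if p_ml_value < 0:
        raise ValueError("p_ml must be non-negative")
    return STOP_LOSS_FRACTION * p_ml_value


@dataclass(frozen=True)
class LoFRateModel:
    """The five components, their sum and the resulting mu_lof.

    Components are held at full precision; rounding to three decimals is a
    reporting concern only.
    """

    p_stop: float
    p_fs: float
    p_ss: float
    p_ml: float
    p_sl: float
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        for name in ("p_stop", "p_fs", "p_ss", "p_ml", "p_sl"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} outside [0, 1]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    @property
    def multiplier(self) -> float:
        """Exact sum of the five components (no internal re-rounding)."""
        return self.p_fs + self.p_stop + self.p_ss + self.p_sl + self.p_ml

    @property
    def mu_lof(self) -> float:
        """Per-site per-generation LoF rate: multiplier * mu."""
        return self.multiplier * self.mu

    @classmethod
    def from_preset(cls, name: str = "paper2025", mu: float = DEFAULT_MU):
        comp = PRESET_COMPONENTS[name]
        return cls(mu=mu, **comp)

    @classmethod
    def from_data(
        cls,
        usage: CodonUsage,
        spectrum: MutationSpectrum,
        n_genes: int,
        total_introns: int,
        sum_cds_lengths: int,
        mu: float = DEFAULT_MU,
    ) -> "LoFRateModel":
        """Assemble the full rate model from its raw inputs."""
        ps = p_stop(usage, spectrum.kappa)
        pml = p_ml(n_genes, sum_cds_lengths)
        return cls(
            p_stop=ps,
            p_fs=p_fs(spectrum, ps),
            p_ss=p_ss(total_introns, sum_cds_lengths),
            p_ml=pml,
            p_sl=p_sl(pml),
            mu=mu,
        )

    def report(self) -> dict[str, float]:
        """Component report with 3-decimal components, full-precision rates."""
        return {
            "p_fs": round(self.p_fs, 3),
            "p_stop": round(self.p_stop, 3),
            "p_ss": round(self.p_ss, 3),
            "p_sl": round(self.p_sl, 3),
            "p_ml": round(self.p_ml, 3),
            "multiplier": self.multiplier,
            "mu": self.mu,
            "mu_lof": self.mu_lof,
        }


def mu_lof(components: tuple[float, float, float, float, float], mu: float) -> float:
    """LoF rate from explicit components (p_fs, p_stop, p_ss, p_sl, p_ml)."""
    if any(c < 0 or c > 1 for c in components):
        raise ValueError("components must lie in [0, 1]")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return sum(components) * mu
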