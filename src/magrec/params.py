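"""Simulation parameters.

Defaults describe a scaled hybrid diploid: eight chromosomes totalling
2 Mb, two parental haplotypes diverged at 0.7% SNP density, a dispersed
repeat family (Ty-like, identical copies) as the NAHR substrate, and an
rDNA-like tandem array on the last chromosome.  Breaks are induced at the
MboI motif (5'-GATC-3') and repaired through a weighted outcome spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

OUTCOMES = (
    "religation",
    "NHEJ_TL",
    "CO",
    "NCO",
    "SGC",
    "BIR",
    "NAHR",
    "tandem_DUP",
    "chrom_loss",
    "chrom_gain",
)

_DEFAULT_LENGTHS = (300_000, 280_000, 260_000, 250_000, 240_000, 230_000, 220_000, 220_000)

# Mitotic spectrum: half the cuts religate cleanly; the rest spread over
# NHEJ translocation, LOH (SGC/BIR), NAHR, tandem duplication, aneuploidy.
_MITOTIC_WEIGHTS = {
    "religation": 0.50,
    "NHEJ_TL": 0.10,
    "CO": 0.0,
    "NCO": 0.0,
    "SGC": 0.15,
    "BIR": 0.08,
    "NAHR": 0.07,
    "tandem_DUP": 0.05,
    "chrom_loss": 0.03,
    "chrom_gain": 0.02,
}

# Meiotic spectrum: interhomolog CO/NCO dominate, with occasional
# meiosis-I nondisjunction (modelled by the chrom_loss/chrom_gain weights).
_MEIOTIC_WEIGHTS = {
    "religation": 0.35,
    "NHEJ_TL": 0.0,
    "CO": 0.36,
    "NCO": 0.22,
    "SGC": 0.0,
    "BIR": 0.0,
    "NAHR": 0.0,
    "tandem_DUP": 0.0,
    "chrom_loss": 0.035,
    "chrom_gain": 0.035,
}


@dataclass
class SimParams:
    """All knobs of the forward simulator; a fixed seed fixes every output."""

    n_chromosomes: int = 8
    chrom_lengths: tuple[int, ...] = _DEFAULT_LENGTHS
    snp_density: float = 0.007
    repeat_copies: int = 12
    repeat_length: int = 4_000
    rdna_unit_length: int = 2_000
    rdna_copy_number: int = 20
    centromere_positions: tuple[int, ...] | None = None  # default: 40% of each length
    cut_motif: str = "GATC"
    cut_probability: float = 0.0008  # per shared motif site, per molecule
    outcome_weights: dict[str, float] | None = None  # default depends on mode
    mean_depth: float = 30.0
    marker_noise: float = 0.002  # per-read allele miscall probability
    junction_support: float = 10.0  # mean split reads per true junction
    depth_bin: int = 1_000
    nco_mean_len: int = 2_000  # geometric mean tract length (bp)
    min_event_spacing: int = 8_000  # same-molecule spacing of allelic breakpoints
    exact_depth: bool = False  # True: counts/depth are exact expectations
    seed: int = 0
    mode: str = "mitotic"  # "mitotic" | "meiotic"

    def __post_init__(self) -> None:
        if self.outcome_weights is None:
            base = _MEIOTIC_WEIGHTS if self.mode == "meiotic" else _MITOTIC_WEIGHTS
            self.outcome_weights = dict(base)
        if self.centromere_positions is None:
            self.centromere_positions = tuple(int(0.4 * L) for L in self.chrom_lengths)
        self.chrom_lengths = tuple(int(x) for x in self.chrom_lengths)
        self.centromere_positions = tuple(int(x) for x in self.centromere_positions)
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("mitotic", "meiotic"):
            raise ValueError(f"mode must be mitotic or meiotic, got {self.mode!r}")
        if self.n_chromosomes < 1 or len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must list one length per chromosome")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("all chromosome lengths must be positive")
        if not (0.0 <= self.snp_density < 1.0):
            raise ValueError("snp_density must be in [0, 1)")
        if not self.cut_motif:
            raise ValueError("cut_motif must be non-empty")
        if set(self.cut_motif) - set("ACGT"):
            raise ValueError("cut_motif must be over the ACGT alphabet")
        if len(self.centromere_positions) != self.n_chromosomes:
            raise ValueError("one centromere position per chromosome required")
        for L, c in zip(self.chrom_lengths, self.centromere_positions):
            if not (0 < c < L):
                raise ValueError("centromere position outside chromosome")
        unknown = set(self.outcome_weights) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes in weights: {sorted(unknown)}")
        w = [self.outcome_weights.get(k, 0.0) for k in OUTCOMES]
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("outcome_weights must be non-negative and sum to 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        if not (0.0 <= self.marker_noise < 1.0):
            raise ValueError("marker_noise must be in [0, 1)")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        roman = (
            "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI "
            "XVII XVIII XIX XX".split()
        )
        if self.n_chromosomes <= len(roman):
            return tuple(f"chr{r}" for r in roman[: self.n_chromosomes])
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    def with_(self, **kw) -> "SimParams":
        """Copy with replacements (re-validates)."""
        return replace(self, **kw)
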