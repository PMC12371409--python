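"""Transcription units, promoters, resource pools and the toxin mechanism config.

A lysate-based cell-free expression (CFE) reaction is described here as a set
of *transcription units* (every transcribable cassette on every plasmid,
including the kanamycin-resistance marker that rides along on each vector)
drawing on shared pools of RNA polymerases (native sigma-70 holoenzyme and
phage T7 RNAP as separate pools), ribosomes, ribonucleases, NTPs and amino
acids.  A lumped "toxin" state variable models the build-up of inhibitory
by-products of expression that shuts translation (or transcription) down past
a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PromoterSpec",
    "TranscriptionUnitSpec",
    "ResourceSpec",
    "ToxinConfig",
    "PROMOTER_NAMES",
    "TOXIN_VARIANTS",
    "default_promoters",
    "default_registry",
]

PROMOTER_NAMES = ("T7_strong", "T7_weak", "sig70_strong", "sig70_weak", "kanR_native")
POLYMERASE_CLASSES = ("T7", "native")
TOXIN_VARIANTS = ("TX_TX", "TL_TL", "TL_TX", "TX_TL", "off")
READOUT_KINDS = ("mature_protein", "free_rna", "none")


@dataclass(frozen=True)
class PromoterSpec:
    """A promoter class with its polymerase pool and binding kinetics.

    ``kf_tx``/``kr_tx`` are the default association (1/(nM s)) and
    dissociation (1/s) rates of the cognate polymerase; a ParameterSet entry
    ``kf_tx_<name>``/``kr_tx_<name>`` overrides them at compile time.
    """

    name: str
    polymerase_class: str
    kf_tx: float
    kr_tx: float

    def __post_init__(self) -> None:
        if self.name not in PROMOTER_NAMES:
            raise ValueError(f"unknown promoter name {self.name!r}")
        if self.polymerase_class not in POLYMERASE_CLASSES:
            raise ValueError(f"unknown polymerase class {self.polymerase_class!r}")
        if not self.kf_tx > 0:
            raise ValueError("kf_tx must be > 0")
        if self.kr_tx < 0:
            raise ValueError("kr_tx must be >= 0")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant kr/kf (nM); smaller = stronger."""
        return self.kr_tx / self.kf_tx


@dataclass(frozen=True)
class TranscriptionUnitSpec:
    """One transcribable construct (a "plasmid" in the dose-response sense).

    ``cargo`` names the gene class carried by the unit (sfGFP, aptamer, empty,
    kanR); units sharing a cargo share mRNA-level kinetics (ribosome binding,
    nuclease binding, degradation, maturation) and the corresponding named
    parameters (``kf_rbs_<cargo>`` etc.) override the fields stored here.
    """

    id: str
    promoter: PromoterSpec
    transcript_length: int
    translatable: bool
    protein_length: int = 0
    kf_rbs: float = 0.0
    kr_rbs: float = 0.0
    kf_nuc: float = 0.0
    kr_nuc: float = 0.0
    k_deg: float = 0.0
    k_mat: float = 0.0
    readout: str = "none"
    cargo: str = ""

    def __post_init__(self) -> None:
        if self.transcript_length <= 0:
            raise ValueError(f"unit {self.id!r}: transcript_length must be > 0")
        if self.translatable and self.protein_length <= 0:
            raise ValueError(f"unit {self.id!r}: translatable units need protein_length > 0")
        if not self.translatable and self.protein_length != 0:
            raise ValueError(f"unit {self.id!r}: untranslated unit must have protein_length 0")
        for name in ("kf_rbs", "kr_rbs", "kf_nuc", "kr_nuc", "k_deg", "k_mat"):
            if getattr(self, name) < 0:
                raise ValueError(f"unit {self.id!r}: {name} must be >= 0")
        if self.readout not in READOUT_KINDS:
            raise ValueError(f"unit {self.id!r}: unknown readout {self.readout!r}")
        if not self.cargo:
            object.__setattr__(self, "cargo", self.id)


@dataclass(frozen=True)
class ResourceSpec:
    """Initial concentrations of the shared machinery and substrate pools.

    Concentrations in nM; NTP0/AA0 are lumped pools in nM-nucleotide and
    nM-residue.  K_NTP/K_AA are half-saturation constants of the elongation
    rate laws.
    """

    RNAP0_native: float = 30.0
    RNAP0_T7: float = 60.0
    Ribo0: float = 800.0
    RNase0: float = 10.0
    NTP0: float = 2.0e7
    AA0: float = 4.0e7
    K_NTP: float = 1.0e5
    K_AA: float = 1.0e5

    def __post_init__(self) -> None:
        for name in ("RNAP0_native", "RNAP0_T7", "Ribo0", "RNase0", "NTP0", "AA0", "K_NTP", "K_AA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ToxinConfig:
    """Lumped toxin mechanism: d[toxin]/dt = (source-rate sum) - b.

    The variant encodes which flux generates the toxin and which resource it
    degrades: e.g. TL_TL = generated by translation, degrades ribosomes.  Past
    ``toxin_threshold`` the target resource is degraded at
    ``k_toxin * (1 + tanh([toxin] - threshold)) * [target]`` — a smooth
    near-step switch.  ``b`` (nM/s) is the lysate's buffering capacity.
    """

    variant: str = "TL_TL"
    b: float = 0.0
    k_toxin: float = 0.0
    toxin_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in TOXIN_VARIANTS:
            raise ValueError(f"unknown toxin variant {self.variant!r}")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.k_toxin < 0:
            raise ValueError("k_toxin must be >= 0")

    @property
    def source(self) -> str | None:
        """Which flux feeds the toxin pool: 'TX', 'TL' or None."""
        if self.variant == "off":
            return None
        return self.variant.split("_")[0]

    @property
    def target(self) -> str | None:
        """Which resource the toxin degrades: 'TX' (both RNAPs) or 'TL' (ribosomes)."""
        if self.variant == "off":
            return None
        return self.variant.split("_")[1]


def default_promoters() -> dict[str, PromoterSpec]:
    """The five promoter classes with nominal binding kinetics.

    Defaults respect the affinity ordering used for screening: T7 strong binds
    T7 RNAP more tightly than T7 weak; sigma-70 weak binds native RNAP more
    weakly than sigma-70 strong.  kanR_native is the constitutive promoter of
    the kanamycin-resistance marker (native polymerase).
    """
    return {
        "T7_strong": PromoterSpec("T7_strong", "T7", kf_tx=1e-2, kr_tx=1e-2),
        "T7_weak": PromoterSpec("T7_weak", "T7", kf_tx=1e-2, kr_tx=1.0),
        "sig70_strong": PromoterSpec("sig70_strong", "native", kf_tx=1e-2, kr_tx=5e-2),
        "sig70_weak": PromoterSpec("sig70_weak", "native", kf_tx=1e-2, kr_tx=5.0),
        "kanR_native": PromoterSpec("kanR_native", "native", kf_tx=1e-2, kr_tx=0.5),
    }


# Construct lengths (nt / aa).  sfGFP CDS ~720 nt plus UTRs; kanR ~816 nt;
# the 3WJdB aptamer and the empty-vector cryptic transcript are short
# untranslated RNAs.  The empty-vector RNA is the shortest, hence the fastest
# to degrade once nuclease-bound.
_LENGTHS = {
    "sfGFP": (870, 239),
    "aptamer": (200, 0),
    "empty": (120, 0),
    "kanR": (816, 271),
}


def default_registry(promoters: dict[str, PromoterSpec] | None = None) -> list[TranscriptionUnitSpec]:
    """The default 10-unit construct registry.

    sfGFP on all four reporter promoters, the 3WJdB aptamer on three (sigma-70
    weak is excluded: its aptamer signal is indistinguishable from noise),
    empty vectors on T7 strong and sigma-70 strong, and one pooled kanR marker
    unit on its native promoter — 10 transcription units in total.

    mRNA-level kinetic defaults encode the screening heuristics: reporter
    mRNAs (sfGFP, aptamer) bind ribonucleases more weakly than kanR/empty
    RNA (stabilising UTR structure), and the short empty-vector RNA has the
    largest catalytic degradation constant.
    """
    proms = promoters or default_promoters()
    units: list[TranscriptionUnitSpec] = []
    mrna_kin = {
        # cargo: (kf_nuc, kr_nuc, k_deg)
        "sfGFP": (1e-2, 0.1, 0.05),
        "aptamer": (1e-2, 0.1, 0.05),
        "empty": (1e-2, 1e-3, 0.3),
        "kanR": (1e-2, 1e-3, 0.08),
    }
    rbs_kin = {"sfGFP": (1e-3, 0.1), "kanR": (1e-3, 0.1)}
    for prom in ("T7_strong", "T7_weak", "sig70_strong", "sig70_weak"):
        units.append(
            TranscriptionUnitSpec(
                id=f"sfGFP_{prom}",
                promoter=proms[prom],
                transcript_length=_LENGTHS["sfGFP"][0],
                translatable=True,
                protein_length=_LENGTHS["sfGFP"][1],
                kf_rbs=rbs_kin["sfGFP"][0],
                kr_rbs=rbs_kin["sfGFP"][1],
                kf_nuc=mrna_kin["sfGFP"][0],
                kr_nuc=mrna_kin["sfGFP"][1],
                k_deg=mrna_kin["sfGFP"][2],
                k_mat=1.5e-3,
                readout="mature_protein",
                cargo="sfGFP",
            )
        )
    for prom in ("T7_strong", "T7_weak", "sig70_strong"):
        units.append(
            TranscriptionUnitSpec(
                id=f"aptamer_{prom}",
                promoter=proms[prom],
                transcript_length=_LENGTHS["aptamer"][0],
                translatable=False,
                kf_nuc=mrna_kin["aptamer"][0],
                kr_nuc=mrna_kin["aptamer"][1],
                k_deg=mrna_kin["aptamer"][2],
                readout="free_rna",
                cargo="aptamer",
            )
        )
    for prom in ("T7_strong", "sig70_strong"):
        units.append(
            TranscriptionUnitSpec(
                id=f"empty_{prom}",
                promoter=proms[prom],
                transcript_length=_LENGTHS["empty"][0],
                translatable=False,
                kf_nuc=mrna_kin["empty"][0],
                kr_nuc=mrna_kin["empty"][1],
                k_deg=mrna_kin["empty"][2],
                readout="none",
                cargo="empty",
            )
        )
    units.append(
        TranscriptionUnitSpec(
            id="kanR",
            promoter=proms["kanR_native"],
            transcript_length=_LENGTHS["kanR"][0],
            translatable=True,
            protein_length=_LENGTHS["kanR"][1],
            kf_rbs=rbs_kin["kanR"][0],
            kr_rbs=rbs_kin["kanR"][1],
            kf_nuc=mrna_kin["kanR"][0],
            kr_nuc=mrna_kin["kanR"][1],
            k_deg=mrna_kin["kanR"][2],
            readout="none",
            cargo="kanR",
        )
    )
    return units
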