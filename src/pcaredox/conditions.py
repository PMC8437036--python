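"""Experimental condition descriptions and the strain/redox-couple registries.

A *condition* is one well or culture tube: a strain (or cell-free control),
the supplied terminal electron acceptor (TEA), and the starting redox state
of the phenazine-1-carboxylic acid (PCA) pool.  Strain capabilities decide
which reactions the kinetic simulator switches on: whether the cells can
catalyze PCA_red oxidation with a given TEA, and whether they reduce PCA_ox
when no oxidation-stimulating TEA is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

TEAS = ("nitrate", "nitrite", "none")
PCA_STATES = ("reduced", "oxidized", "none")

ABIOTIC = "abiotic"


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition (a well or a tube).

    Parameters
    ----------
    strain : str
        Strain identifier, or ``"abiotic"`` for the cell-free control.
    tea : {"nitrate", "nitrite", "none"}
        Supplied terminal electron acceptor.
    pca_start : {"reduced", "oxidized", "none"}
        Redox state of the PCA pool at t = 0.
    pca_total : float
        Total PCA concentration in uM (default 200).
    tea_conc : float
        Supplied TEA concentration in uM (default 10000, i.e. 10 mM).
    can_oxidize_with : frozenset of str
        TEAs with which this strain catalyzes PCA_red oxidation.
    can_reduce_pca : bool
        Whether the strain reduces PCA_ox in the absence of a
        stimulating TEA.
    replicate : int
        Biological replicate index (1-based).
    """

    strain: str
    tea: str
    pca_start: str
    pca_total: float = 200.0
    tea_conc: float = 10000.0
    can_oxidize_with: frozenset = field(default_factory=frozenset)
    can_reduce_pca: bool = False
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.tea not in TEAS:
            raise ValueError(f"unknown TEA {self.tea!r}; expected one of {TEAS}")
        if self.pca_start not in PCA_STATES:
            raise ValueError(
                f"unknown pca_start {self.pca_start!r}; expected one of {PCA_STATES}"
            )
        if self.pca_total < 0:
            raise ValueError("pca_total must be >= 0")
        if self.tea_conc < 0:
            raise ValueError("tea_conc must be >= 0")
        object.__setattr__(self, "can_oxidize_with", frozenset(self.can_oxidize_with))
        if self.abiotic and (self.can_oxidize_with or self.can_reduce_pca):
            raise ValueError("abiotic conditions must have no biotic capabilities")

    @property
    def abiotic(self) -> bool:
        return self.strain == ABIOTIC


#: Capabilities of the strains assayed: TEAs that stimulate PCA_red oxidation,
#: and whether the strain reduces PCA_ox without such a TEA.  The two
#: pseudomonads oxidize with nitrite but not nitrate; the enterics and
#: P. aeruginosa oxidize with nitrate.
STRAIN_CAPABILITIES: dict[str, tuple[frozenset, bool]] = {
    "C. portucalensis MBL": (frozenset({"nitrate"}), True),
    "E. coli MG1655": (frozenset({"nitrate"}), True),
    "P. aeruginosa dPhz*": (frozenset({"nitrate"}), True),
    "P. chlororaphis": (frozenset({"nitrite"}), True),
    "P. aureofaciens": (frozenset({"nitrite"}), True),
    ABIOTIC: (frozenset(), False),
}

DEFAULT_STRAINS = tuple(STRAIN_CAPABILITIES)


def condition(
    strain: str,
    tea: str,
    pca_start: str,
    *,
    replicate: int = 1,
    pca_total: float = 200.0,
    tea_conc: float = 10000.0,
) -> ConditionSpec:
    """Build a ConditionSpec, filling capabilities from the strain registry.

    Unregistered strain names get no capabilities (behave abiotically);
    register custom strains by passing a ConditionSpec directly instead.
    """
    ox, red = STRAIN_CAPABILITIES.get(strain, (frozenset(), False))
    if strain == ABIOTIC:
        ox, red = frozenset(), False
    return ConditionSpec(
        strain=strain,
        tea=tea,
        pca_start=pca_start,
        pca_total=pca_total,
        tea_conc=tea_conc,
        can_oxidize_with=ox,
        can_reduce_pca=red,
        replicate=replicate,
    )


def make_condition_matrix(
    strains: Sequence[str],
    teas: Sequence[str] = TEAS,
    pca_states: Sequence[str] = ("reduced", "oxidized"),
    replicates: int = 3,
    *,
    pca_total: float = 200.0,
    tea_conc: float = 10000.0,
) -> list[ConditionSpec]:
    """Full-factorial condition design: strains x TEAs x PCA states x replicates.

    The default design over the six registered biological entries (five
    strains plus the abiotic control), three TEAs, two PCA starting states
    and three replicates yields 108 specs.  Duplicate strain names are
    deduplicated with a warning; an empty strain list is rejected.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    strains = list(strains)
    if not strains:
        raise ValueError("at least one strain is required")
    seen: list[str] = []
    for s in strains:
        if s in seen:
            warnings.warn(f"duplicate strain {s!r} dropped from design", stacklevel=2)
        else:
            seen.append(s)
    specs: list[ConditionSpec] = []
    for strain in seen:
        for tea in teas:
            for pca_state in pca_states:
                for rep in range(1, replicates + 1):
                    specs.append(
                        condition(
                            strain,
                            tea,
                            pca_state,
                            replicate=rep,
                            pca_total=pca_total,
                            tea_conc=tea_conc,
                        )
                    )
    return specs


def default_condition_matrix(replicates: int = 3) -> list[ConditionSpec]:
    """The assay's standard 6 x 3 x 2 x `replicates` design (108 wells)."""
    return make_condition_matrix(DEFAULT_STRAINS, replicates=replicates)


@dataclass(frozen=True)
class RedoxCouple:
    """A half-reaction with its midpoint potential at pH 7 (mV vs NHE)."""

    name: str
    e_mid: float


#: Midpoint potentials at pH 7 versus the normal hydrogen electrode.
REDOX_COUPLES: dict[str, RedoxCouple] = {
    "PCA": RedoxCouple("PCA", -116.0),
    "NO3-/NO2-": RedoxCouple("NO3-/NO2-", +433.0),
    "NO2-/NO": RedoxCouple("NO2-/NO", +350.0),
}


def get_couple(name_or_couple) -> RedoxCouple:
    if isinstance(name_or_couple, RedoxCouple):
        return name_or_couple
    try:
        return REDOX_COUPLES[name_or_couple]
    except KeyError:
        raise KeyError(
            f"unknown redox couple {name_or_couple!r}; "
            f"registered: {sorted(REDOX_COUPLES)}"
        ) from None


__all__ = [
    "ConditionSpec",
    "RedoxCouple",
    "REDOX_COUPLES",
    "STRAIN_CAPABILITIES",
    "DEFAULT_STRAINS",
    "TEAS",
    "PCA_STATES",
    "ABIOTIC",
    "condition",
    "make_condition_matrix",
    "default_condition_matrix",
    "get_couple",
]
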