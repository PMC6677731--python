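"""Checkpoint receptor-ligand binding, signal integration and tumor subtype lattice.

The molecular layer of the simulator.  Receptor-ligand pairs (checkpoint
*axes*, e.g. ``PD1-PDL1``) engage inside the small volume of the
immunological synapse.  Binding is treated at equilibrium: the paper-style
inputs are surface densities (molecules per cell), a dissociation constant
``Kd`` (molar) and the synapse volume (liters).  A blocking antibody at its
local free concentration shifts the equilibrium competitively.

The combined inhibitory effect of several simultaneously engaged axes is a
Chou-Talalay-type median-effect sum: each axis contributes its receptor
occupancy ``RO`` normalised by the maximum occupancy ``RO_max`` attainable
on that axis, weighted by the ``RO_max`` values themselves, and the sum is
pushed through a Hill function.  The result ``f_a`` lies in [0, 1/2]; a
single axis saturated at its own maximum yields exactly 1/2.

Tumor heterogeneity in checkpoint expression is a lattice of 2^n cancer-cell
subtypes: with n independently distributed checkpoints at expression
fractions f_i, the subtype expressing exactly the set S carries weight
prod_{i in S} f_i * prod_{i not in S} (1 - f_i).  The lattice is constant in
time - killing removes cells proportionally from every subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214076e23

__all__ = [
    "CheckpointAxis",
    "SignalIntegrationParams",
    "SubtypeLattice",
    "AntibodyBindingSpec",
    "receptor_occupancy",
    "competitive_occupancy",
    "integrate_signals",
    "build_subtype_lattice",
    "BLOCKED_AXES",
]

#: Axes neutralised by each antibody class.  Anti-PD-1 masks PD-1 itself and
#: therefore blocks both of its ligand interactions; anti-PD-L1 masks PD-L1
#: but cannot touch the PD-1:PD-L2 interaction; anti-CTLA-4 masks CTLA-4.
BLOCKED_AXES = {
    "antiPD1": frozenset({"PD1-PDL1", "PD1-PDL2"}),
    "antiPDL1": frozenset({"PD1-PDL1", "CD80-PDL1"}),
    "antiCTLA4": frozenset({"CTLA4-CD80", "CTLA4-CD86"}),
}

_DRUG_TARGET = {"antiPD1": "PD1", "antiPDL1": "PDL1", "antiCTLA4": "CTLA4"}


@dataclass
class CheckpointAxis:
    """One receptor-ligand signaling interaction.

    ``name`` follows the ``RECEPTOR-LIGAND`` convention (e.g. ``PD1-PDL1``).
    Densities are molecules per interacting cell pair, ``kd`` is molar and
    ``synapse_volume`` is the liter volume in which the species interact.
    ``ro`` is the current occupancy and ``ro_max`` its drug-free maximum.
    """

    name: str
    receptor_density: float
    ligand_density: float
    kd: float
    synapse_volume: float
    ro: float = 0.0
    ro_max: float = 1.0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.synapse_volume <= 0:
            raise ValueError(f"axis {self.name}: kd and synapse_volume must be > 0")
        if self.receptor_density < 0 or self.ligand_density < 0:
            raise ValueError(f"axis {self.name}: densities must be >= 0")
        if not (0.0 <= self.ro <= self.ro_max + 1e-12 and self.ro_max <= 1.0):
            raise ValueError(f"axis {self.name}: need 0 <= ro <= ro_max <= 1")

    @property
    def receptor_name(self) -> str:
        return self.name.split("-")[0]

    @property
    def ligand_name(self) -> str:
        return self.name.split("-")[1]

    def drug_free_occupancy(self) -> float:
        """Equilibrium occupancy with no antibody present (defines RO_max)."""
        return receptor_occupancy(
            self.receptor_density, self.ligand_density, self.kd, self.synapse_volume
        )


@dataclass
class SignalIntegrationParams:
    """Inputs of the combined-effect calculation: Hill coefficient m > 1 and
    the axes whose occupancies are being integrated."""

    m: float
    axes: list[CheckpointAxis] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("Hill coefficient m must be > 1")


@dataclass
class AntibodyBindingSpec:
    """A checkpoint antibody: what it binds and which axes that neutralises."""

    drug: str
    kd_ab: float
    target: str = ""
    blocked_axes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.drug not in BLOCKED_AXES:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {sorted(BLOCKED_AXES)}")
        if self.kd_ab <= 0:
            raise ValueError("kd_ab must be > 0")
        if not self.target:
            self.target = _DRUG_TARGET[self.drug]
        if not self.blocked_axes:
            self.blocked_axes = BLOCKED_AXES[self.drug]


@dataclass
class SubtypeLattice:
    """2^n cancer-cell subtypes indexed by checkpoint-expression bitmask.

    Bit i of a subtype's index is set iff the subtype expresses
    ``checkpoint_names[i]``.  ``weights`` is the constant fraction of the
    tumor occupied by each subtype.
    """

    checkpoint_names: list[str]
    fractions: np.ndarray
    weights: np.ndarray

    @property
    def n_subtypes(self) -> int:
        return len(self.weights)

    def expresses(self, mask: int, checkpoint: str) -> bool:
        return bool(mask >> self.checkpoint_names.index(checkpoint) & 1)

    def expression_matrix(self) -> np.ndarray:
        """(2^n, n) boolean matrix: entry [s, i] = subtype s expresses checkpoint i."""
        n = len(self.checkpoint_names)
        masks = np.arange(2**n)[:, None]
        return (masks >> np.arange(n) & 1).astype(bool)


def receptor_occupancy(
    receptor_total: float, ligand_total: float, kd: float, synapse_volume: float
) -> float:
    """Bound-receptor fraction from exact two-species equilibrium in a volume.

    Solves ``R + L <-> C`` with ``Kd = [R][L]/[C]`` for total copy numbers
    ``receptor_total`` and ``ligand_total`` confined to ``synapse_volume``;
    returns ``C / R_total``.  The quadratic root is written in its
    numerically stable form (no cancellation for weak binding).
    """
    if kd <= 0 or synapse_volume <= 0:
        raise ValueError("kd and synapse_volume must be > 0")
    if receptor_total < 0 or ligand_total < 0:
        raise ValueError("molecule counts must be >= 0")
    if receptor_total == 0 or ligand_total == 0:
        return 0.0
    r0 = receptor_total / (AVOGADRO * synapse_volume)
    l0 = ligand_total / (AVOGADRO * synapse_volume)
    b = r0 + l0 + kd
    # stable quadratic: c = 2*r0*l0 / (b + sqrt(b^2 - 4 r0 l0))
    c = 2.0 * r0 * l0 / (b + np.sqrt(b * b - 4.0 * r0 * l0))
    return float(c / r0)


def competitive_occupancy(
    axis: CheckpointAxis, antibody_conc: float, spec: AntibodyBindingSpec
) -> float:
    """Axis occupancy under competitive antibody binding.

    The antibody is present at its bulk free concentration (it is not
    depleted by synapse binding, whose mass is negligible compared to the
    tissue pool).  Masking either partner of the axis at fixed antibody
    concentration rescales the axis Kd by ``1 + [Ab]/Kd_ab``, so the
    three-species competition collapses to the two-species quadratic with an
    effective Kd.  An axis the drug does not block is returned unchanged.
    """
    if antibody_conc < 0:
        raise ValueError("antibody_conc must be >= 0")
    if spec.target not in (axis.receptor_name, axis.ligand_name):
        if axis.name in spec.blocked_axes:
            raise ValueError(
                f"drug {spec.drug} declares {axis.name} blocked but targets "
                f"{spec.target}, which is not a member of the axis"
            )
        return axis.drug_free_occupancy()
    if axis.name not in spec.blocked_axes:
        return axis.drug_free_occupancy()
    kd_eff = axis.kd * (1.0 + antibody_conc / spec.kd_ab)
    return receptor_occupancy(
        axis.receptor_density, axis.ligand_density, kd_eff, axis.synapse_volume
    )


def integrate_signals(params: SignalIntegrationParams) -> float:
    """Combined fractional effect f_a of simultaneously engaged axes.

    ``f_a = S^m / (1 + S^m)`` with ``S = sum_i w_i (RO/RO_max)_i`` and
    ``w_i = RO_max,i / sum_j RO_max,j``.  Because each ratio is at most 1 and
    the weights sum to 1, S <= 1 and f_a <= 1/2.
    """
    ro_max = np.array([a.ro_max for a in params.axes], dtype=float)
    ro = np.array([a.ro for a in params.axes], dtype=float)
    total = ro_max.sum()
    if total <= 0.0:
        warnings.warn("all axes have ro_max = 0; combined signal is 0", stacklevel=2)
        return 0.0
    active = ro_max > 0
    s = float(np.sum(ro_max[active] / total * (ro[active] / ro_max[active])))
    sm = s**params.m
    return float(sm / (1.0 + sm))


def build_subtype_lattice(fractions: dict[str, float]) -> SubtypeLattice:
    """Independent-expression subtype lattice from per-checkpoint fractions.

    With checkpoints expressed equally and independently across the tumor,
    the 2^n subtype weights are the Bernoulli product measure of the
    expression fractions.
    """
    names = list(fractions)
    f = np.asarray([fractions[k] for k in names], dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("expression fractions must lie in [0, 1]")
    n = len(names)
    masks = np.arange(2**n)[:, None]
    bits = (masks >> np.arange(n)) & 1
    weights = np.prod(np.where(bits == 1, f, 1.0 - f), axis=1)
    return SubtypeLattice(checkpoint_names=names, fractions=f, weights=weights)
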