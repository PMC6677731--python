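"""Default parameterisation: checkpoint panel, antibody PK sets, patient.

The per-axis receptor/ligand densities, dissociation constants and synapse
volume below are literature-typical surrogate values (checkpoint ectodomain
affinities are in the low-micromolar range; synapse copy numbers of order
10^3; an immunological synapse encloses roughly 1e-15 L).  The antibody PK
sets approximate published population pharmacokinetics of nivolumab
(anti-PD-1), durvalumab (anti-PD-L1) and ipilimumab (anti-CTLA-4): half-life
of two to four weeks, central volume near plasma volume.  All values are
config-overridable surrogates, not fitted constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .checkpoints import (
    AntibodyBindingSpec,
    CheckpointAxis,
    SubtypeLattice,
    build_subtype_lattice,
)
from .immune import (
    AntigenCycleParameters,
    KillingParameters,
    PrimingParameters,
    TraffickingParameters,
    TumorGeometry,
    TumorGrowthParameters,
)
from .pbpk import PkParameters, TmddParameters

__all__ = [
    "SYNAPSE_VOLUME_L",
    "default_killing_axes",
    "default_priming_axes",
    "default_cd28_axis",
    "default_antibody_specs",
    "default_pk_parameters",
    "CheckpointPanel",
    "PatientParameters",
    "ModelParams",
]

SYNAPSE_VOLUME_L = 1.0e-15

#: tumor-side killing axes: receptor on the effector, ligand on the cancer
#: cell (or either partner cancer-expressed for PD1-PDL1).  Which lattice
#: checkpoints must be expressed for an axis to be engaged on a subtype:
KILLING_AXIS_GATES: dict[str, tuple[str, ...]] = {
    "PD1-PDL1": ("PDL1",),     # engaged from either orientation; PD1 gate added below
    "PD1-PDL2": ("PDL2",),
    "CD80-PDL1": ("CD80", "PDL1"),
}


def default_killing_axes() -> list[CheckpointAxis]:
    """Inhibitory axes acting in the cancer-cell / effector synapse."""
    return [
        CheckpointAxis("PD1-PDL1", receptor_density=3.0e3, ligand_density=8.0e3,
                       kd=8.2e-6, synapse_volume=SYNAPSE_VOLUME_L),
        CheckpointAxis("PD1-PDL2", receptor_density=3.0e3, ligand_density=2.0e3,
                       kd=2.3e-6, synapse_volume=SYNAPSE_VOLUME_L),
        CheckpointAxis("CD80-PDL1", receptor_density=1.0e3, ligand_density=8.0e3,
                       kd=1.7e-6, synapse_volume=SYNAPSE_VOLUME_L),
    ]


def default_priming_axes() -> list[CheckpointAxis]:
    """Inhibitory axes acting in the mAPC / T-cell priming synapse."""
    return [
        CheckpointAxis("CTLA4-CD80", receptor_density=5.0e2, ligand_density=1.0e3,
                       kd=4.0e-7, synapse_volume=SYNAPSE_VOLUME_L),
        CheckpointAxis("CTLA4-CD86", receptor_density=5.0e2, ligand_density=1.5e3,
                       kd=2.6e-6, synapse_volume=SYNAPSE_VOLUME_L),
    ]


def default_cd28_axis() -> CheckpointAxis:
    """Costimulatory CD28:CD80/86 axis; its drug-free occupancy is SigCD28."""
    return CheckpointAxis("CD28-CD8086", receptor_density=5.0e3, ligand_density=1.0e4,
                          kd=4.0e-6, synapse_volume=SYNAPSE_VOLUME_L)


def default_antibody_specs() -> dict[str, AntibodyBindingSpec]:
    return {
        "antiPD1": AntibodyBindingSpec(drug="antiPD1", kd_ab=4.5e-9),
        "antiPDL1": AntibodyBindingSpec(drug="antiPDL1", kd_ab=1.0e-9),
        "antiCTLA4": AntibodyBindingSpec(drug="antiCTLA4", kd_ab=3.5e-9),
    }


def default_pk_parameters() -> dict[str, PkParameters]:
    common = dict(
        v_central=3.5, v_tight=6.3, v_leaky=2.6, v_lymph=5.2,
        lymph_flow_tight=1.0, lymph_flow_leaky=1.9,
        sigma_tight=0.95, sigma_leaky=0.70, sigma_lymph=0.20,
        tumor_perm_in=0.025, tumor_perm_out=0.10,
    )
    return {
        "antiPD1": PkParameters(drug="antiPD1", clearance=0.23,
                                infusion_hours=1.0, **common),
        "antiPDL1": PkParameters(drug="antiPDL1", clearance=0.30,
                                 infusion_hours=1.0, **common),
        "antiCTLA4": PkParameters(
            drug="antiCTLA4", clearance=0.38, infusion_hours=1.5,
            tmdd=TmddParameters(k_syn=2.0e-9, k_deg=0.2, k_int=2.0, kd=1.2e-8),
            **common,
        ),
    }


def panel_from_yaml(path: str | None = None) -> "CheckpointPanel":
    """Load a checkpoint panel from YAML (package default panel if no path)."""
    import yaml

    if path is None:
        from importlib.resources import files

        text = (files("icbsim") / "data" / "checkpoint_panel.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    v = float(raw.get("synapse_volume", SYNAPSE_VOLUME_L))

    def axes(section: dict) -> list[CheckpointAxis]:
        return [
            CheckpointAxis(name, receptor_density=float(d["receptor_density"]),
                           ligand_density=float(d["ligand_density"]),
                           kd=float(d["kd"]), synapse_volume=v)
            for name, d in section.items()
        ]

    cd28_name, cd28_d = next(iter(raw["cd28_axis"].items()))
    return CheckpointPanel(
        killing_axes=axes(raw["killing_axes"]),
        priming_axes=axes(raw["priming_axes"]),
        cd28_axis=CheckpointAxis(
            cd28_name, receptor_density=float(cd28_d["receptor_density"]),
            ligand_density=float(cd28_d["ligand_density"]),
            kd=float(cd28_d["kd"]), synapse_volume=v),
        antibodies={
            drug: AntibodyBindingSpec(drug=drug, kd_ab=float(d["kd_ab"]))
            for drug, d in raw["antibodies"].items()
        },
        m=float(raw.get("hill_m", 2.0)),
        expression={k: float(x) for k, x in raw["expression"].items()},
    )


@dataclass
class CheckpointPanel:
    """All molecular-layer inputs: axes, antibody specs, lattice fractions,
    Hill coefficient of the combined-effect curve."""

    killing_axes: list[CheckpointAxis] = field(default_factory=default_killing_axes)
    priming_axes: list[CheckpointAxis] = field(default_factory=default_priming_axes)
    cd28_axis: CheckpointAxis = field(default_factory=default_cd28_axis)
    antibodies: dict[str, AntibodyBindingSpec] = field(default_factory=default_antibody_specs)
    m: float = 2.0  # Hill coefficient, > 1
    #: tumor checkpoint expression fractions; PDL1 is patient-varied
    expression: dict[str, float] = field(
        default_factory=lambda: {"PD1": 0.05, "PDL1": 0.65, "PDL2": 0.10, "CD80": 0.05}
    )
    #: coupling strength of f_a on the priming flux and on killing
    priming_inhibition_strength: float = 1.4
    killing_inhibition_strength: float = 1.6
    #: weight with which tumor Tregs/MDSCs present PD-L1 to effectors
    regulatory_ligand_potency: float = 30.0
    #: residual resistance of cancer cells expressing none of the modeled
    #: checkpoints (unmodeled inhibitory pathways scale their killability)
    unexpressed_resistance: float = 0.25

    def lattice(self) -> SubtypeLattice:
        return build_subtype_lattice(self.expression)


@dataclass
class PatientParameters:
    """The varied physiological parameters defining one virtual patient,
    plus the fixed per-patient constants."""

    tumor_diameter_start: float = 47.5   # mm, range [15, 80]
    antigen_strength: float = 0.9        # [0.8, 1.0] for melanoma
    t_clonality: float = 70.0            # [10, 130]
    treg_ln_frac: float = 0.20           # [0.05, 0.35] of TDLN T cells
    treg_tumor_frac: float = 0.00125     # [0, 0.0025] of cancer cells
    mdsc_multiplier: float = 3.0         # [2, 4]
    pdl1_frac: float = 0.65              # [0.40, 0.90]
    antigen_per_cell: float = 100.0
    chemokine_factor: float = 200.0      # [50, 500] in sensitivity analyses
    body_weight: float = 75.0            # kg

    RANGES = {
        "tumor_diameter_start": (15.0, 80.0),
        "antigen_strength": (0.8, 1.0),
        "t_clonality": (10.0, 130.0),
        "treg_ln_frac": (0.05, 0.35),
        "treg_tumor_frac": (0.0, 0.0025),
        "mdsc_multiplier": (2.0, 4.0),
        "pdl1_frac": (0.40, 0.90),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self.RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside documented range [{lo}, {hi}]")


@dataclass
class ModelParams:
    """Full parameterisation of one virtual patient's simulation."""

    patient: PatientParameters = field(default_factory=PatientParameters)
    priming: PrimingParameters = field(default_factory=PrimingParameters)
    killing: KillingParameters = field(default_factory=KillingParameters)
    trafficking: TraffickingParameters = field(default_factory=TraffickingParameters)
    antigen: AntigenCycleParameters = field(default_factory=AntigenCycleParameters)
    growth: TumorGrowthParameters = field(default_factory=TumorGrowthParameters)
    geometry: TumorGeometry = field(default_factory=TumorGeometry)
    panel: CheckpointPanel = field(default_factory=CheckpointPanel)
    pk: dict[str, PkParameters] = field(default_factory=default_pk_parameters)
    #: TDLN drug exposure relative to the tumor compartment concentration
    ln_tumor_conc_ratio: float = 0.35
    ln_volume_ml: float = 0.5            # for mAPC density readouts

    def __post_init__(self) -> None:
        # patient-level values propagate into the mechanistic blocks
        self.priming = replace(
            self.priming,
            antigen_strength=self.patient.antigen_strength,
            t_clonality=self.patient.t_clonality,
        )
        self.antigen = replace(self.antigen, antigen_per_cell=self.patient.antigen_per_cell)
        expr = dict(self.panel.expression)
        expr["PDL1"] = self.patient.pdl1_frac
        self.panel = replace(self.panel, expression=expr)

    @classmethod
    def for_patient(cls, patient: PatientParameters, **overrides) -> "ModelParams":
        return cls(patient=patient, **overrides)

    def capacity_cells(self) -> float:
        from .immune import diameter_to_cells

        return diameter_to_cells(self.growth.capacity_diameter_mm, self.geometry)
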