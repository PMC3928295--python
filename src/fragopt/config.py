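"""Run configuration with validation.

All fields are validated before any computation starts, so a malformed
run fails immediately rather than mid-scan.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator


class PolarizationConfig(BaseModel):
    """Induced-dipole solver settings (atomic units)."""

    model_config = ConfigDict(extra="forbid")

    tolerance: float = Field(1.0e-10, gt=0.0, description="max dipole change, a.u.")
    max_iter: int = Field(200, ge=1)
    damping: Literal["none", "thole"] = "none"
    thole_a: float = Field(0.39, gt=0.0)
    solver: Literal["jacobi", "dense"] = "jacobi"
    # Whether the total induction energy spans all fragments or only the
    # buffer + active domains during FDD runs.
    span: Literal["all", "active_buffer"] = "all"


class RunConfig(BaseModel):
    """Top-level settings for an energy, gradient, optimization or scan run."""

    model_config = ConfigDict(extra="forbid")

    backend: str = "mock"
    rhf_basis: str = "6-31G(d)"
    mp2_basis: str = "cc-pVDZ"
    #: unitless relative pair distance (vdW-scaled) below which a pair is
    #: computed quantum mechanically
    dimer_cutoff: float = Field(1.5, gt=0.0)
    polarization_enabled: bool = True
    fdd_enabled: bool = True
    hybrid_mp2: bool = True
    #: Hartree/Bohr
    gradient_tolerance: float = Field(1.0e-4, gt=0.0)
    convergence_metric: Literal["max", "rms"] = "max"
    max_opt_steps: int = Field(200, ge=1)
    #: kcal·mol⁻¹·Å⁻²
    restraint_force_constant: float = Field(500.0, ge=0.0)
    random_seed: int = 0
    #: optional HDF5 cache store, loaded before and saved after a run
    cache_path: str | None = None
    pol: PolarizationConfig = Field(default_factory=PolarizationConfig)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.hybrid_mp2 and not self.mp2_basis:
            raise ValueError("hybrid_mp2 requires mp2_basis to be set")
        return self

    def basis_for(self, fragment_id: int, high_level: int) -> str:
        """Per-fragment basis: the MP2 basis on H, the RHF basis elsewhere."""
        if self.hybrid_mp2 and fragment_id == high_level:
            return self.mp2_basis
        return self.rhf_basis
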