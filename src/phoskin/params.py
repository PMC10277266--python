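"""Parameter containers shared by the single-pass and multi-pass models.

Units are fixed project-wide: hours, litres, mmol/L, L/h. There is no unit
conversion layer.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SPParameters", "MPParameters", "Q_ZERO_THRESHOLD"]

#: Ultrafiltration flows below this (L/h) are treated as exactly zero; the
#: Q > 0 closed forms raise to a power (Ks+Kb)/Q that overflows as Q -> 0
#: while the limit is exact.
Q_ZERO_THRESHOLD = 1e-10


@dataclass(frozen=True, kw_only=True)
class SPParameters:
    """Kinetic constants for one single-pass dialysis session.

    Attributes
    ----------
    Ks : float
        Source-to-serum phosphate transfer rate (L/h).
    Kb : float
        Dialyzer diffusion clearance (L/h).
    Cs : float
        Source ("deep compartment") concentration, constant during a
        session (mmol/L).
    Vb0 : float
        Initial serum + extracellular volume (L).
    x0 : float
        Initial serum concentration (mmol/L).
    Q : float
        Ultrafiltration flow (L/h); shrinks the patient-side volume as
        ``Vb(t) = Vb0 - Q t``.
    Cd0 : float
        Fixed dialysate-side concentration (mmol/L); effectively zero in
        standard single-pass treatment.
    """

    Ks: float
    Kb: float
    Cs: float
    Vb0: float
    x0: float
    Q: float = 0.0
    Cd0: float = 0.0

    def __post_init__(self) -> None:
        if self.Ks < 0:
            raise ValueError(f"Ks must be >= 0, got {self.Ks}")
        # Kb = 0 (no clearance) is admitted at the type level so limiting
        # cases are expressible; solvers that divide by Kb reject it.
        if self.Kb < 0:
            raise ValueError(f"Kb must be >= 0, got {self.Kb}")
        if self.Q < 0:
            raise ValueError(f"Q must be >= 0, got {self.Q}")
        if self.Vb0 <= 0:
            raise ValueError(f"Vb0 must be > 0, got {self.Vb0}")
        for name in ("Cs", "x0", "Cd0"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    @property
    def q_is_zero(self) -> bool:
        """Whether ultrafiltration is below the zero-dispatch threshold."""
        return self.Q < Q_ZERO_THRESHOLD


@dataclass(frozen=True, kw_only=True)
class MPParameters(SPParameters):
    """Multi-pass session parameters: single-pass constants plus the
    recirculated-dialysate compartment.

    Attributes
    ----------
    Vd0 : float
        Initial dialysate volume (L); grows as ``Vd(t) = Vd0 + Q t``.
    y0 : float
        Initial dialysate concentration (mmol/L); the dialysate starts
        phosphate-free in practice.
    """

    Vd0: float
    y0: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.Vd0 <= 0:
            raise ValueError(f"Vd0 must be > 0, got {self.Vd0}")
        if self.y0 < 0:
            raise ValueError(f"y0 must be >= 0, got {self.y0}")
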