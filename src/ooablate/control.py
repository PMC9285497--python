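"""Discrete PI regulation of the electrode r.m.s. voltage.

The generator holds the electrode-tip temperature at the control set point
by adjusting the applied r.m.s. voltage:

    V = Kp * (T_target - T_tip) + Ki * integral of (T_target - T_tip) dt

with Kp = 1.15 V/K and Ki = 0.06 V/(K s) by default.  The integral uses a
left-endpoint rectangle rule at the controller update interval (the
heating time step), so the very first update acts with zero accumulated
integral.  The output is clamped at 0 V (the generator cannot apply a
negative r.m.s. voltage); while clamped the integrator is frozen
(anti-windup).  In cooldown mode the output is forced to zero and the
integrator is inert.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PIController"]


@dataclass
class PIController:
    T_target: float  # °C
    Kp: float = 1.15  # V/K
    Ki: float = 0.06  # V/(K s)
    integral: float = 0.0  # K s
    V_rms: float = 0.0  # V, last output
    clamped: bool = False
    heating: bool = True

    def update(self, tip_T: float, dt: float) -> float:
        """Next r.m.s. voltage given the current tip temperature."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if not self.heating:
            self.V_rms = 0.0
            return 0.0
        error = self.T_target - tip_T
        v = self.Kp * error + self.Ki * self.integral
        if v < 0.0:
            self.V_rms = 0.0
            self.clamped = True  # integrator frozen while clamped at zero
        else:
            self.V_rms = v
            self.clamped = False
            self.integral += error * dt
        return self.V_rms

    def cooldown_mode(self) -> "PIController":
        """Switch the generator off: zero output, inert integrator."""
        self.heating = False
        self.V_rms = 0.0
        return self
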