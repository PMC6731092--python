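"""Optogenetic stimulation protocol description shared by generators and analysis."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StimProtocol:
    """Laser stimulation protocol for one recording block.

    ``constant`` means a single continuous light step of ``train_duration``;
    ``pulsed`` means a pulse train (``frequency`` Hz, ``pulse_width`` s pulses)
    lasting ``train_duration``.  Trials are separated by
    ``inter_trial_interval`` of darkness.  Defaults follow the standard
    in vivo protocol: 1 s stimulation repeated for 30 trials with a 4 s
    inter-stimulation interval; pulsed trains use 10 ms pulses at 5 or 20 Hz.
    """

    pattern: str = "constant"
    train_duration: float = 1.0
    pulse_width: float = 0.010
    frequency: float = 20.0
    n_trials: int = 30
    inter_trial_interval: float = 4.0

    def __post_init__(self) -> None:
        if self.pattern not in ("constant", "pulsed"):
            raise ValueError(f"unknown stimulation pattern {self.pattern!r}")
        if not self.train_duration > 0:
            raise ValueError("train_duration must be positive")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.inter_trial_interval < 0:
            raise ValueError("inter_trial_interval must be non-negative")
        if self.pattern == "pulsed":
            if not (self.pulse_width > 0 and self.frequency > 0):
                raise ValueError("pulsed pattern needs positive pulse_width and frequency")
            if self.frequency * self.pulse_width > 1.0:
                raise ValueError("duty cycle exceeds 1: frequency * pulse_width > 1")

    @property
    def trial_period(self) -> float:
        """Onset-to-onset spacing in seconds."""
        return self.train_duration + self.inter_trial_interval

    def trial_onsets(self, first_onset: float = 0.0):
        """Laser onset time of each trial, in session time."""
        import numpy as np

        return first_onset + np.arange(self.n_trials) * self.trial_period
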