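"""Synthetic compound tables with the statistical structure the analysis assumes.

Two generators make every downstream stage testable without the original
per-compound descriptor table:

- :func:`simulate_descriptor_table` draws class-conditional independent
  Gaussian descriptor values at configurable group means/SDs. The defaults
  are the published group summaries of the seven retained descriptors over
  38 attractants and 15 non-attractants (e.g. q-: attractant -300 +/- 31
  kJ/mol vs non-attractant -269 +/- 36). A redundancy spec can append noisy
  copies of chosen descriptors so the rank-correlation filter has real
  collinearity to remove.

- :func:`simulate_aspartate_set` draws analog compounds with an
  inter-carboxyl distance R uniform on a range, labels them attractant when
  R lies below a true threshold (with a configurable exception rate
  emulating the one published outlier), and gives attractants a sensitivity
  linear in R with a negative slope plus an amino-group potency boost;
  K_D = 10^(-sensitivity) so the log-transform is exactly invertible.

All randomness flows through one seeded generator per call: the same seed
reproduces a table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import CompoundRecord, LabeledTable, ValidationError

__all__ = [
    "DescriptorSynthConfig",
    "AspartateSynthConfig",
    "TABLE2_CLASS_MOMENTS",
    "simulate_descriptor_table",
    "simulate_aspartate_set",
]

#: (attractant (mu, sd), non-attractant (mu, sd)) per retained descriptor —
#: the published two-group summaries used as generator defaults
TABLE2_CLASS_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "E": ((-596.0, 233.0), (-566.0, 186.0)),
    "E_sol": ((-74.0, 18.0), (-61.0, 16.0)),
    "E_H-E_L": ((-10.6, 1.0), (-10.4, 1.0)),
    "D": ((2.5, 1.1), (1.8, 0.7)),
    "q-": ((-300.0, 31.0), (-269.0, 36.0)),
    "q_ion-": ((50.3, 6.4), (51.7, 4.5)),
    "q+": ((196.0, 31.0), (198.0, 13.0)),
}


@dataclass
class DescriptorSynthConfig:
    seed: int
    n_attractant: int = 38
    n_non_attractant: int = 15
    class_moments: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: {k: v for k, v in TABLE2_CLASS_MOMENTS.items()}
    )
    #: (source descriptor, number of copies, Gaussian noise SD) triples
    redundancy_spec: list[tuple[str, int, float]] = field(default_factory=list)

    def validate(self) -> "DescriptorSynthConfig":
        if self.n_attractant < 2 or self.n_non_attractant < 2:
            raise ValidationError("need >= 2 compounds per class")
        for name, ((m1, s1), (m2, s2)) in self.class_moments.items():
            if s1 <= 0 or s2 <= 0:
                raise ValidationError(f"SDs for {name!r} must be > 0")
        for src, copies, noise in self.redundancy_spec:
            if src not in self.class_moments:
                raise ValidationError(f"redundancy source {src!r} unknown")
            if copies < 1 or noise < 0:
                raise ValidationError("copies >= 1 and noise SD >= 0 required")
        return self


def simulate_descriptor_table(config: DescriptorSynthConfig) -> LabeledTable:
    """Class-conditional Gaussian descriptor table, deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n1, n0 = config.n_attractant, config.n_non_attractant
    n = n1 + n0
    labels = ["attractant"] * n1 + ["non_attractant"] * n0

    columns: dict[str, np.ndarray] = {}
    for name, ((m1, s1), (m0, s0)) in config.class_moments.items():
        col = np.empty(n)
        col[:n1] = rng.normal(m1, s1, size=n1)
        col[n1:] = rng.normal(m0, s0, size=n0)
        columns[name] = col
    for src, copies, noise in config.redundancy_spec:
        for c in range(1, copies + 1):
            columns[f"{src}_dup{c}"] = columns[src] + rng.normal(0.0, noise, size=n)

    names = tuple(columns)
    records = [
        CompoundRecord(
            serial_id=i + 1,
            name=f"synthetic-{i + 1}",
            label=labels[i],
            descriptors={d: float(columns[d][i]) for d in names},
        )
        for i in range(n)
    ]
    # duplicated columns are not in the default dictionary: register ad hoc
    from .core_data import DescriptorDictionary, DescriptorEntry

    schema = DescriptorDictionary(entries=tuple(
        DescriptorEntry(d, d, "") for d in names
    ))
    return LabeledTable(records, names, schema=schema).validate()


@dataclass
class AspartateSynthConfig:
    seed: int
    n_compounds: int = 17
    r_range: tuple[float, float] = (2.9, 6.5)       # Å
    r_threshold_true: float = 4.0                    # Å
    sensitivity_intercept: float = 7.4               # -log10 M at R = 0
    sensitivity_slope: float = -1.2                  # per Å, must be negative
    noise_sd: float = 1.0                            # -log10 M units
    nh2_effect: float = 1.8                          # potency boost, -log10 M
    nh2_probability: float = 0.5
    label_exception_rate: float = 1.0 / 17.0         # oxaloacetate-like flips

    def validate(self) -> "AspartateSynthConfig":
        if self.n_compounds < 1:
            raise ValidationError("need at least one compound")
        lo, hi = self.r_range
        if not (0 < lo < hi):
            raise ValidationError("r_range must be an increasing positive interval")
        if self.sensitivity_slope >= 0:
            raise ValidationError("sensitivity_slope must be negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for p in (self.nh2_probability, self.label_exception_rate):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")
        return self


def _ncarbon_from_r(r: float, threshold: float) -> int:
    # coarse structural proxy: chain length grows with the carboxyl spacing
    if r < threshold:
        return 2
    if r < threshold + 1.5:
        return 3
    return 4


def simulate_aspartate_set(config: AspartateSynthConfig) -> LabeledTable:
    """Analog set with a planted negative R-sensitivity relation."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    lo, hi = config.r_range
    r = rng.uniform(lo, hi, size=n)
    truth = (r < config.r_threshold_true).astype(int)
    flip = rng.random(n) < config.label_exception_rate
    label = np.where(flip, 1 - truth, truth)
    nh2 = (rng.random(n) < config.nh2_probability).astype(int)
    noise = rng.normal(0.0, config.noise_sd, size=n)

    records = []
    for i in range(n):
        attract = bool(label[i])
        k_d = None
        if attract:
            s = (
                config.sensitivity_intercept
                + config.sensitivity_slope * r[i]
                + config.nh2_effect * nh2[i]
                + noise[i]
            )
            k_d = float(10.0 ** (-s))
        records.append(CompoundRecord(
            serial_id=i + 1,
            name=f"analog-{i + 1}",
            label="attractant" if attract else "non_attractant",
            k_d=k_d,
            n_carboxyl=2,
            n_carbon=_ncarbon_from_r(float(r[i]), config.r_threshold_true),
            n_nh2=int(nh2[i]),
            r_distance=float(r[i]),
        ))
    return LabeledTable(records, ()).validate()
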