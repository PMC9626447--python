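"""Bundled parameter fixtures: literature constants, measured length
statistics, and the calibrated shape/rate coefficients per phenotype.

Each value carries a source tag so the provenance of every constant in a
run is auditable.  The derived quantities (k1, psi, a_max, k2, S_max)
are *not* stored: :func:`phenotype_parameters` recomputes them through
:func:`linecell.model_core.derive_parameters`, which reproduces the
published values from the constraints.
"""

from __future__ import annotations

from .model_core import (
    REC,
    TEC,
    UEC,
    BaseConstants,
    ModelParameters,
    PhenotypeStats,
    derive_parameters,
    equilibrium_actin,
)

__all__ = [
    "BASE_CONSTANTS",
    "STATS",
    "OPTIMIZED",
    "PUBLISHED_DERIVED",
    "PSI_UEC_PRINTED",
    "SOURCE_TAGS",
    "phenotype_parameters",
    "default_initial_conditions",
]

#: Literature constants shared by all phenotypes.
BASE_CONSTANTS = BaseConstants(k=347.0, a_h=0.2, v_p=25.0, phi=3e-2,
                               c_h=10.0, c_L=1.0, a_min=0.05)

#: Measured length statistics per phenotype.  Tumbling durations:
#: T_P = 1 h 14 min, T_I = 2 h 33 min.
STATS: dict[str, PhenotypeStats] = {
    REC: PhenotypeStats(label=REC, n_cells=12, L_max=70.5, L_min=31.4,
                        L_mean=50.1, beta=1.6),
    UEC: PhenotypeStats(label=UEC, n_cells=13, L_max=314.6, L_min=101.9,
                        L_mean=185.5, beta=2.2),
    TEC: PhenotypeStats(label=TEC, n_cells=17, L_max=64.1, L_min=13.1,
                        T_P=74 * 60.0, T_I=153 * 60.0, beta=2.1),
}

#: Calibrated (swarm-optimized) shape and rate coefficients.
OPTIMIZED: dict[str, dict[str, float]] = {
    TEC: {"M1": 7.4e4, "M2": 6.4, "M3": 1e-5, "lam": 8.75e-4, "c_eq": 2.26},
    REC: {"M1": 2.15e2, "M2": 1.6e-2, "M3": 8.5e-4, "lam": 8.75e-4,
          "c_eq": 8.07},
    UEC: {"M1": 2.15e2, "M2": 1.6e-2, "M3": 8.5e-4, "lam": 8.75e-4,
          "c_eq": 8.07},
}

#: Published values of the derived constants, kept for side-by-side
#: reporting (``linecell derive``) and regression tests.
PUBLISHED_DERIVED: dict[str, dict[str, float]] = {
    TEC: {"k1": 1.04e3, "k2": 142.2, "psi": 5.6e3, "a_min": 5e-2,
          "a_sat": 2.5e-2},
    REC: {"k1": 1.04e3, "k2": 404.0, "psi": 2.4e3, "a_min": 5e-2,
          "a_sat": 2.5e-2},
    UEC: {"k1": 1.04e3, "k2": 351.8, "psi": 725.1, "a_min": 5e-2,
          "a_sat": 2.5e-2},
}

#: The UEC contractility constant as printed (752 /mM^2/s).  It is
#: inconsistent with the L_min constraint (which gives ~725.1) and with
#: the printed k2 = 351.8; the recomputed value is used throughout and
#: the printed one retained here for the audit trail.
PSI_UEC_PRINTED = 752.0

SOURCE_TAGS: dict[str, str] = {
    "k": "baseline table, F-actin polymerization rate",
    "a_h": "baseline table, F-actin homeostatic value",
    "v_p": "baseline table, protrusion velocity",
    "phi": "baseline table, friction coefficient",
    "c_L": "baseline table, minimum ATP concentration",
    "c_h": "baseline table, homeostatic ATP concentration",
    "a_min": "baseline table, F-actin literature range (lower bound)",
    "L_min/L_max/L_mean/T_P/T_I/beta": "measured length statistics table",
    "M1/M2/M3/lam/c_eq": "calibrated-values table (swarm-optimized)",
    "k1/k2/psi/a_sat/S_max": "derived from constraints (recomputed)",
}


def phenotype_parameters(label: str,
                         base: BaseConstants = BASE_CONSTANTS) -> ModelParameters:
    """Full baseline parameter set for one phenotype."""
    return derive_parameters(STATS[label], base, **OPTIMIZED[label])


def default_initial_conditions(p: ModelParameters) -> tuple[float, float, float]:
    """Default initial state ``(a, L, c)`` per phenotype.

    TEC starts rounded (minimum F-actin and length); REC/UEC start at
    their elongated equilibrium.  ATP starts at the intermediate value
    ``(c_h + c_L)/2``.
    """
    c0 = 0.5 * (p.atp.c_h + p.atp.c_L)
    if p.phenotype == TEC:
        return p.actin.a_min, p.length.L_min, c0
    a0 = equilibrium_actin(p.actin.k2, p)
    stats = STATS[p.phenotype]
    return a0, float(stats.L_mean), c0
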