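"""Published MM-GBSA component means for the BRD4/BRD9 inhibitor complexes.

These are the reported ensemble-averaged components (kcal/mol, mean and
standard deviation over 400 snapshots) for the inhibitors H1B, JQ1 and TVU
bound to bromodomains BRD4 and BRD9.  They are *inputs* to the aggregation
and cross-system comparison bookkeeping -- the package recomputes every
derived quantity (dGpol, dGbind, component deltas) from them at run time.
"""

from __future__ import annotations

from .energetics import (BindingFreeEnergy, aggregate_binding_free_energy,
                         components_from_means)

__all__ = ["BRD4_TABLE", "BRD9_TABLE", "binding_energy", "all_systems"]

# (mean, std) per component; minus_t_ds under "-TdS"; experimental dG where reported
BRD4_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "H1B": {"dele": (-29.97, 9.39), "dvdw": (-41.78, 3.38), "dggb": (42.71, 7.61),
            "dgsurf": (-5.70, 0.44), "-TdS": (18.65, 5.52)},
    "JQ1": {"dele": (-22.91, 15.93), "dvdw": (-28.51, 7.13), "dggb": (33.53, 15.38),
            "dgsurf": (-3.50, 0.90), "-TdS": (15.01, 6.13), "dGexp": (-10.00, 0.0)},
    "TVU": {"dele": (-34.45, 9.84), "dvdw": (-44.36, 2.92), "dggb": (48.59, 7.69),
            "dgsurf": (-5.97, 0.33), "-TdS": (19.34, 6.15)},
}

BRD9_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "H1B": {"dele": (-43.82, 7.69), "dvdw": (-48.74, 2.89), "dggb": (52.35, 6.15),
            "dgsurf": (-6.29, 0.30), "-TdS": (25.11, 4.35), "dGexp": (-10.16, 0.0)},
    "JQ1": {"dele": (15.43, 9.03), "dvdw": (-40.37, 4.25), "dggb": (-2.66, 8.85),
            "dgsurf": (-4.58, 0.41), "-TdS": (20.24, 3.75)},
    "TVU": {"dele": (-39.46, 4.91), "dvdw": (-50.03, 3.28), "dggb": (50.06, 4.22),
            "dgsurf": (-6.33, 0.29), "-TdS": (22.58, 4.15), "dGexp": (-11.35, 0.0)},
}


def binding_energy(protein: str, inhibitor: str) -> BindingFreeEnergy:
    """Aggregate the published component means into a BindingFreeEnergy."""
    table = {"BRD4": BRD4_TABLE, "BRD9": BRD9_TABLE}[protein]
    row = table[inhibitor]
    comp = components_from_means(row["dele"][0], row["dvdw"][0],
                                 row["dggb"][0], row["dgsurf"][0])
    dg_exp = row["dGexp"][0] if "dGexp" in row else None
    return aggregate_binding_free_energy(comp, row["-TdS"][0],
                                         entropy_method="supplied", dg_exp=dg_exp)


def all_systems() -> dict[tuple[str, str], BindingFreeEnergy]:
    return {(p, i): binding_energy(p, i)
            for p in ("BRD4", "BRD9") for i in ("H1B", "JQ1", "TVU")}
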