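"""Model parameters for the WUS-HAM-CLV3 network.

One flat dataclass holds every rate and Hill constant of the ten-species
model.  The three epidermal morphogens (the cytokinin proxy ``L_c``, the AHK
repressor proxy ``L_a`` and the HAM repressor ``L_H``) have their production,
degradation and diffusion rates named ``p_Lc/g_Lc/D_Lc`` etc. to keep them
distinct from the CLV3-peptide parameters ``p_c/g_c/D_c`` (the two groups are
easy to conflate because both describe diffusing signals).

RNA degradation rates ``g_W``, ``g_H``, ``g_C`` only enter through the
equilibrium ratio production/degradation and default to 1, so the maximal
production rates ``V_W``, ``V_H``, ``V_C`` directly set the equilibrium
expression scales.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace


#: parameters optimised in each stage of the fitting pipeline
STAGE_PARAMS = {
    1: ("k_LcW", "k_LaW", "p_Lc", "D_Lc", "g_Lc", "p_La", "D_La", "g_La"),
    2: ("k_c", "p_c", "D_c"),
    3: ("k_LH", "p_LH", "D_LH", "p_w", "D_w", "p_h", "D_h", "f", "D_d",
        "V_C", "k_w", "k_d", "g_h", "g_w", "g_d", "b"),
    4: ("k_LH", "p_LH", "D_LH", "p_w", "D_w", "p_h", "D_h", "f", "D_d",
        "V_C", "k_w", "k_d", "g_h", "g_w", "g_d", "b"),
    5: ("p_c", "D_c", "g_c"),
}

#: constants never optimised (2D model)
FIXED_2D = {"V_W": 4.0, "n_LcW": 8.0, "n_LaW": 4.0, "n_c": 2.0,
            "V_H": 1.0, "n_LH": 4.0}

#: Hill coefficients held fixed for optimisations on 3D templates
FIXED_3D_HILL = {"n_LcW": 7.25968619416, "n_LaW": 1.99109438845,
                 "n_c": 6.66419523049, "n_LH": 6.0}


@dataclass
class ModelParameters:
    """All rate constants of the ten-equation model."""

    # --- transcription
    V_W: float = 4.0      # max WUS transcription
    k_LcW: float = 1.0    # cytokinin activation threshold on WUS
    n_LcW: float = 8.0
    k_LaW: float = 1.0    # AHK-repressor threshold on WUS
    n_LaW: float = 4.0
    k_c: float = 1.0      # CLV3-peptide repression threshold on WUS
    n_c: float = 2.0
    g_W: float = 1.0
    V_H: float = 1.0      # max HAM transcription
    k_LH: float = 1.0     # epidermal HAM-repressor threshold
    n_LH: float = 4.0
    g_H: float = 1.0
    V_C: float = 1.0      # max CLV3 transcription (Shea-Ackers promoter)
    k_w: float = 1.0      # WUS-monomer association constant on CLV3 promoter
    k_d: float = 1.0      # HAM-WUS-dimer association constant
    g_C: float = 1.0

    # --- proteins / peptide / dimer
    p_w: float = 1.0      # WUS translation
    g_w: float = 1.0
    D_w: float = 1.0
    p_h: float = 1.0      # HAM translation
    g_h: float = 1.0
    D_h: float = 1.0
    g_d: float = 1.0      # dimer degradation
    D_d: float = 1.0
    f: float = 1.0        # dimer association
    b: float = 1.0        # dimer dissociation
    p_c: float = 1.0      # CLV3 peptide production
    g_c: float = 1.0
    D_c: float = 1.0

    # --- epidermal morphogens
    p_Lc: float = 1.0     # cytokinin proxy
    g_Lc: float = 1.0
    D_Lc: float = 1.0
    p_La: float = 1.0     # AHK repressor proxy
    g_La: float = 1.0
    D_La: float = 1.0
    p_LH: float = 1.0     # HAM repressor
    g_LH: float = 1.0
    D_LH: float = 1.0

    # --- variant switches
    variant: str = "heterodimer"          # or "homodimer" (WUS-WUS dimer)
    clv3_feedback: bool = True            # False models the clavata mutant
    pclv3_wus: bool = False               # WUS driven by the CLV3 promoter
    sink_free_species: tuple = ()         # species with the sink replaced by no-flux

    def validate(self) -> None:
        for fld in fields(self):
            if fld.type == "float":
                v = getattr(self, fld.name)
                if v < 0:
                    raise ValueError(f"parameter {fld.name} must be >= 0: {v}")
        for name in ("n_LcW", "n_LaW", "n_c", "n_LH"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Hill coefficient {name} must be > 0")

    def copy(self, **updates) -> "ModelParameters":
        return replace(self, **updates)

    # -- flat key-value serialisation ------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for name, value in self.to_dict().items():
                if name == "sink_free_species":
                    value = ",".join(value)
                elif isinstance(value, float):
                    value = repr(float(value))
                fh.write(f"{name}\t{value}\n")

    @classmethod
    def load(cls, path) -> "ModelParameters":
        d: dict = {}
        with open(path) as fh:
            for raw in fh:
                if not raw.strip() or raw.startswith("#"):
                    continue
                name, value = raw.rstrip("\n").split("\t")
                if name == "variant":
                    d[name] = value
                elif name in ("clv3_feedback", "pclv3_wus"):
                    d[name] = value == "True"
                elif name == "sink_free_species":
                    d[name] = tuple(s for s in value.split(",") if s)
                else:
                    d[name] = float(value)
        return cls.from_dict(d)
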