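"""A/T2/N staging: map continuous biomarkers to categorical statuses.

Amyloid (A) status comes from the Centiloid value, either in the AMYPAD
three-class scheme (CL < 10 negative, 10-30 intermediate, > 30 positive;
the interval is read as closed, so CL = 10 and CL = 30 are intermediate) or
with the common binary 24.1 CL cut (CL = 24.1 counts as positive).  Tau
(T2) status uses the CenTauR cut: CTRz < 2 is negative, 2 or above
positive.  Neurodegeneration (N) uses the HAVAs probability with a strict
0.5 cut: exactly 0.5 is negative.

The bundled HAVAs model is a clearly-branded surrogate ("surrogate-v1"): a
logistic function of the hippocampal, amygdalar and inferior-lateral-
ventricular ICV fractions' z-scores against a synthetic age-linear
normative table.  It has the right shape (decreasing in hippocampus and
amygdala volume, increasing in ventricular volume, age-adapted midpoint)
but does not reproduce the published lifespan-model parameters; a real
model can be supplied as a JSON parameter file of the same form.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "StagingThresholds",
    "BiomarkerPanel",
    "a_status",
    "t2_status",
    "n_status",
    "havas_probability",
    "atn_panel",
    "load_havas_model",
]

NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class StagingThresholds:
    cl_low: float = 10.0      # AMYPAD lower cut (A- below)
    cl_high: float = 30.0     # AMYPAD upper cut (A+ above)
    cl_binary: float = 24.1   # legacy binary cut
    ctrz_cut: float = 2.0
    havas_cut: float = 0.5

    def __post_init__(self):
        if not self.cl_low < self.cl_high:
            raise ValueError("cl_low must be below cl_high")
        for v in (self.cl_low, self.cl_high, self.cl_binary, self.ctrz_cut,
                  self.havas_cut):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")


DEFAULT_THRESHOLDS = StagingThresholds()


def a_status(cl: float, mode: str = "amypad",
             thresholds: StagingThresholds = DEFAULT_THRESHOLDS) -> str:
    """Amyloid status from a Centiloid value."""
    if not np.isfinite(cl):
        raise ValueError(f"CL must be finite, got {cl}")
    if mode == "amypad":
        if cl < thresholds.cl_low:
            return "A-"
        if cl <= thresholds.cl_high:
            return "A_inter"
        return "A+"
    if mode == "binary":
        return "A+" if cl >= thresholds.cl_binary else "A-"
    raise ValueError(f"unknown A-status mode {mode!r}")


def t2_status(ctrz: float,
              thresholds: StagingThresholds = DEFAULT_THRESHOLDS) -> str:
    """Tau status: CTRz < 2 negative, else positive."""
    if not np.isfinite(ctrz):
        raise ValueError(f"CTRz must be finite, got {ctrz}")
    return "T2-" if ctrz < thresholds.ctrz_cut else "T2+"


def n_status(havas: float,
             thresholds: StagingThresholds = DEFAULT_THRESHOLDS) -> str:
    """Neurodegeneration status: probability strictly above 0.5 is N+."""
    if not (0.0 <= havas <= 1.0):
        raise ValueError(f"HAVAs probability must be in [0, 1], got {havas}")
    return "N+" if havas > thresholds.havas_cut else "N-"


@lru_cache(maxsize=1)
def _default_havas_model() -> dict:
    path = importlib.resources.files("atnquant").joinpath(
        "data", "havas_surrogate_v1.json")
    with open(str(path)) as f:
        return json.load(f)


def load_havas_model(path: str | Path | None = None) -> dict:
    """Load HAVAs model parameters (defaults to the bundled surrogate)."""
    if path is None:
        return _default_havas_model()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"HAVAs model file not found: {path}")
    with open(path) as f:
        model = json.load(f)
    need = {"hippocampus", "amygdala", "inferior_lateral_ventricle"}
    if set(model.get("structures", {})) != need:
        raise ValueError(f"HAVAs model must define structures {sorted(need)}")
    return model


def havas_probability(hippocampus_icv_frac: float,
                      amygdala_icv_frac: float,
                      inferior_lateral_ventricle_icv_frac: float,
                      age: float,
                      model: dict | None = None) -> float:
    """Neurodegeneration probability from three structure volumes and age.

    z-scores each ICV fraction against the model's age-linear normative
    mean/SD and passes the signed average (volume loss and ventricular
    enlargement both push upward) through a logistic.  At exactly the
    normative means the output is 0.5 for any age.
    """
    fracs = {"hippocampus": hippocampus_icv_frac,
             "amygdala": amygdala_icv_frac,
             "inferior_lateral_ventricle": inferior_lateral_ventricle_icv_frac}
    for k, v in fracs.items():
        if not (0.0 < v < 1.0):
            raise ValueError(f"{k} ICV fraction must be in (0, 1), got {v}")
    if not (18.0 <= age <= 110.0):
        raise ValueError(f"age must be in [18, 110] years, got {age}")
    model = model or load_havas_model()
    ref_age = model.get("reference_age", 40.0)
    zsum = 0.0
    for k, v in fracs.items():
        p = model["structures"][k]
        mean = p["mean_age40"] + p["slope_per_year"] * (age - ref_age)
        z = (v - mean) / p["sd"]
        zsum += p["direction"] * z
    logit = model.get("logistic_scale", 2.0) * zsum / len(fracs)
    return float(expit(logit))


@dataclass
class BiomarkerPanel:
    """Continuous biomarkers plus their categorical A/T2/N statuses."""

    cl: float | None
    ctrz: float | None
    havas: float | None
    a_status: str
    t2_status: str
    n_status: str
    mode: str
    thresholds: StagingThresholds
    amyloid_tracer: str | None = None
    tau_tracer: str | None = None
    havas_model: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "BiomarkerPanel":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        d["thresholds"] = StagingThresholds(**d["thresholds"])
        return cls(**d)


def atn_panel(cl: float | None = None,
              ctrz: float | None = None,
              havas: float | None = None,
              mode: str = "amypad",
              thresholds: StagingThresholds = DEFAULT_THRESHOLDS,
              amyloid_tracer: str | None = None,
              tau_tracer: str | None = None,
              havas_model: str | None = "surrogate-v1") -> BiomarkerPanel:
    """Assemble the A/T2/N panel; a missing modality is 'not_assessed'
    (the pipeline can run without amyloid-PET or without tau-PET)."""
    return BiomarkerPanel(
        cl=cl, ctrz=ctrz, havas=havas,
        a_status=a_status(cl, mode, thresholds) if cl is not None
        else NOT_ASSESSED,
        t2_status=t2_status(ctrz, thresholds) if ctrz is not None
        else NOT_ASSESSED,
        n_status=n_status(havas, thresholds) if havas is not None
        else NOT_ASSESSED,
        mode=mode, thresholds=thresholds,
        amyloid_tracer=amyloid_tracer, tau_tracer=tau_tracer,
        havas_model=havas_model if havas is not None else None)
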