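"""Declarative model + prior configuration (YAML/JSON).

Linear models are declared through the basis-function registry; ODE models
through a registry of named systems (currently the feedback-motif
variants).  Right-hand sides can always be supplied in code instead.

Example linear config::

    model:
      kind: linear
      name: M3
      basis:
        - [poly, 1]
        - [poly, 2]
        - [sin_scaled, 15, 3]
    prior:
      theta_1: {dist: gaussian, xi: 1.0}
      theta_2: {dist: gaussian, xi: 1.0}
      theta_3: {dist: gaussian, xi: 1.0}

Example ODE config::

    model:
      kind: ode
      registry: motif
      variant: 1
    prior:
      k1: {dist: gamma, alpha: 1.0, beta: 3.0}
      sigma: {dist: halfnormal, scale: 1.0}
"""

from __future__ import annotations

import yaml

from .models import (
    GammaPrior,
    GaussianPrior,
    HalfNormalPrior,
    LinearBasisModel,
    PriorSpec,
    make_basis,
)

__all__ = ["load_config", "load_model", "load_prior"]

_PRIOR_DISTS = {
    "gamma": lambda spec: GammaPrior(
        spec.get("alpha", 1.0),
        spec.get("beta", 3.0),
        rate_convention=spec.get("rate_convention", False),
    ),
    "gaussian": lambda spec: GaussianPrior(spec.get("xi", 1.0)),
    "halfnormal": lambda spec: HalfNormalPrior(spec.get("scale", 1.0)),
}


def load_prior(spec: dict) -> PriorSpec:
    priors = {}
    for name, entry in spec.items():
        dist = entry.get("dist")
        if dist not in _PRIOR_DISTS:
            raise ValueError(f"unknown prior distribution {dist!r} for {name!r}")
        priors[name] = _PRIOR_DISTS[dist](entry)
    return PriorSpec(priors)


def load_model(spec: dict):
    kind = spec.get("kind")
    if kind == "linear":
        basis = [make_basis(entry[0], *entry[1:]) for entry in spec["basis"]]
        return LinearBasisModel(basis, name=spec.get("name", "linear"))
    if kind == "ode":
        if spec.get("registry") != "motif":
            raise ValueError("only the 'motif' ODE registry is available")
        from .studies import motif_quartet

        variant = int(spec.get("variant", 1))
        if not 1 <= variant <= 4:
            raise ValueError("motif variant must be 1..4")
        return motif_quartet().models[variant - 1]
    raise ValueError(f"unknown model kind {kind!r}")


def load_config(path):
    """Read a YAML config file and return (model, prior)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    model = load_model(cfg["model"])
    prior = load_prior(cfg["prior"]) if "prior" in cfg else None
    return model, prior
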