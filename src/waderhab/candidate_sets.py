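"""Loading of a-priori candidate model sets from YAML configuration."""

from __future__ import annotations

from importlib import resources

import yaml

from .mmi import CandidateSpec


def _read_config(path=None) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("waderhab") / "config" / "candidate_sets.yaml"
    return yaml.safe_load(ref.read_text())


def load_candidate_set(response_kind: str, response: str,
                       transform: str = "identity",
                       path=None) -> list[CandidateSpec]:
    """Build CandidateSpecs for ``response_kind`` ("effort" | "success").

    ``response`` names the response column; ``transform`` applies to every
    model in the set (e.g. "fourth-root" for stork nesting effort). A
    custom YAML may be supplied via ``path``.
    """
    cfg = _read_config(path)
    if response_kind not in cfg:
        raise KeyError(f"no candidate set {response_kind!r} in config")
    block = cfg[response_kind]
    random_term = block.get("random_intercept")
    return [
        CandidateSpec(response=response, terms=tuple(terms),
                      transform=transform, random_intercept=random_term)
        for terms in block["models"]
    ]
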