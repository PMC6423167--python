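"""XML experiment configuration: load, save, validate.

Script-mode experiments are described by a versioned XML dialect (schema
in ``schema/experiment.xsd``): timing, neuron preset with parameter
overrides, the two directed synapses, integrator, calibration options,
acquisition scaling, the virtual-preparation settings and the seed.
``ExperimentConfig`` round-trips losslessly through this format.

Parameter overrides are flat ``<param name=... value=.../>`` elements;
nested conductance-model parameters use dotted names (``g.Ca``,
``gates.s.tau``).
"""

from __future__ import annotations

from importlib import resources

from lxml import etree

from .experiment_runner import ConfigError, ExperimentConfig

__all__ = ["config_to_xml", "config_from_xml", "load_config", "save_config",
           "validate_xml"]


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def _unflatten(d: dict) -> dict:
    out: dict = {}
    for key, v in d.items():
        parts = key.split(".")
        cur = out
        for p in parts[:-1]:
            cur = cur.setdefault(p, {})
        cur[parts[-1]] = v
    return out


def _parse_value(text: str):
    for cast in (int, float):
        try:
            val = cast(text)
            if cast is int and "." in text:
                continue
            return val
        except ValueError:
            continue
    if text in ("true", "false"):
        return text == "true"
    return text


def _params_el(parent, overrides: dict) -> None:
    for name, value in sorted(_flatten(overrides).items()):
        etree.SubElement(parent, "param", name=name, value=repr(value)
                         if isinstance(value, float) else str(value))


def _params_from(el) -> dict:
    flat = {p.get("name"): _parse_value(p.get("value"))
            for p in el.findall("param")}
    return _unflatten(flat)


def config_to_xml(config: ExperimentConfig) -> etree._Element:
    root = etree.Element("hybrid_experiment", version="1")
    etree.SubElement(root, "timing", fs=repr(config.fs),
                     pre_s=repr(config.pre_s), coupled_s=repr(config.coupled_s),
                     post_s=repr(config.post_s))
    neuron = etree.SubElement(root, "neuron", preset=config.neuron_preset)
    _params_el(neuron, config.neuron_overrides)
    s1 = etree.SubElement(root, "synapse", direction="model_to_live",
                          preset=config.syn_model_to_live)
    _params_el(s1, config.syn_model_to_live_overrides)
    s2 = etree.SubElement(root, "synapse", direction="live_to_model",
                          preset=config.syn_live_to_model)
    _params_el(s2, config.syn_live_to_model_overrides)
    etree.SubElement(root, "integrator", method=config.integrator)
    etree.SubElement(
        root, "calibration",
        target_burst=str(config.target_burst),
        online_refresh=str(config.online_refresh).lower(),
        frac_on=repr(config.frac_on), frac_off=repr(config.frac_off),
        min_gap_s=repr(config.min_gap_s),
        drift_compensation=str(config.drift_compensation).lower(),
        drift_window_s=repr(config.drift_window_s),
        drift_alpha=repr(config.drift_alpha))
    etree.SubElement(root, "scaling", input_factor=repr(config.input_factor),
                     nA_per_V=repr(config.nA_per_V))
    prep = etree.SubElement(
        root, "preparation", preset=config.prep_preset,
        period_s=repr(config.prep_period_s),
        range_min=repr(float(config.prep_range[0])),
        range_max=repr(float(config.prep_range[1])),
        noise_sd=repr(config.prep_noise_sd), drift=repr(config.prep_drift))
    if config.replay_path:
        prep.set("replay_path", config.replay_path)
    etree.SubElement(root, "seeds", master=str(config.seed))
    if config.out_dir:
        etree.SubElement(root, "output", dir=config.out_dir)
    return root


def config_from_xml(root) -> ExperimentConfig:
    if root.tag != "hybrid_experiment":
        raise ConfigError(f"unexpected root element {root.tag!r}")
    try:
        timing = root.find("timing")
        synapses = {s.get("direction"): s for s in root.findall("synapse")}
        cal = root.find("calibration")
        scal = root.find("scaling")
        prep = root.find("preparation")
        neuron = root.find("neuron")
        target = cal.get("target_burst")
        out = root.find("output")
        return ExperimentConfig(
            fs=float(timing.get("fs")),
            pre_s=float(timing.get("pre_s")),
            coupled_s=float(timing.get("coupled_s")),
            post_s=float(timing.get("post_s")),
            neuron_preset=neuron.get("preset"),
            neuron_overrides=_params_from(neuron),
            syn_model_to_live=synapses["model_to_live"].get("preset"),
            syn_model_to_live_overrides=_params_from(synapses["model_to_live"]),
            syn_live_to_model=synapses["live_to_model"].get("preset"),
            syn_live_to_model_overrides=_params_from(synapses["live_to_model"]),
            integrator=root.find("integrator").get("method"),
            target_burst="auto" if target == "auto" else float(target),
            online_refresh=cal.get("online_refresh", "false") == "true",
            frac_on=float(cal.get("frac_on")),
            frac_off=float(cal.get("frac_off")),
            min_gap_s=float(cal.get("min_gap_s")),
            drift_compensation=cal.get("drift_compensation") == "true",
            drift_window_s=float(cal.get("drift_window_s")),
            drift_alpha=float(cal.get("drift_alpha")),
            input_factor=float(scal.get("input_factor")),
            nA_per_V=float(scal.get("nA_per_V")),
            prep_preset=prep.get("preset"),
            prep_period_s=float(prep.get("period_s")),
            prep_range=(float(prep.get("range_min")), float(prep.get("range_max"))),
            prep_noise_sd=float(prep.get("noise_sd")),
            prep_drift=float(prep.get("drift")),
            replay_path=prep.get("replay_path") or None,
            seed=int(root.find("seeds").get("master")),
            out_dir=out.get("dir") if out is not None else None,
        )
    except (AttributeError, KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed experiment XML: {exc}") from exc


def validate_xml(root) -> None:
    """Validate a config tree against the shipped schema; raises on failure."""
    xsd_text = resources.files("hybridclamp").joinpath(
        "schema/experiment.xsd").read_bytes()
    schema = etree.XMLSchema(etree.fromstring(xsd_text))
    schema.assertValid(root)


def load_config(path, validate: bool = True) -> ExperimentConfig:
    tree = etree.parse(str(path))
    root = tree.getroot()
    if validate:
        validate_xml(root)
    return config_from_xml(root)


def save_config(config: ExperimentConfig, path) -> None:
    root = config_to_xml(config)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")
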