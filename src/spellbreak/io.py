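"""HDF5 persistence for sessions, models and attack templates.

Layout (format version 1):

P300 session            SSVEP session
  /meta  attrs            /meta  attrs
  /signal  (C, N)         /blocks/<b>/trials/<t>/signal  (C, N)
  /events  (n, 4)             with attrs freq, char, onset_sample
  /trials  table
  /trial_chars (n,) str

Every file carries ``format_version`` and ``paradigm`` attributes on
``/meta``; payload datasets round-trip byte-stable.  Reading re-validates
the structural invariants (stimulus-id permutations, z-normalization,
per-block frequency uniqueness) and raises descriptive errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import attack_p300, attack_ssvep, p300, synth

FORMAT_VERSION = 1


def file_sha256(path: str | Path) -> str:
    """Content hash used to chain artifact provenance (session -> model
    -> template)."""
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()

__all__ = [
    "write_session",
    "read_session",
    "write_p300_model",
    "read_p300_model",
    "write_p300_template",
    "read_p300_template",
    "write_ssvep_template",
    "read_ssvep_template",
    "load_config",
]


def _meta(group: h5py.Group, paradigm: str, **attrs) -> None:
    meta = group.create_group("meta")
    meta.attrs["format_version"] = FORMAT_VERSION
    meta.attrs["paradigm"] = paradigm
    for k, v in attrs.items():
        meta.attrs[k] = v


def _check_version(f: h5py.File, path: str | Path) -> str:
    if "meta" not in f:
        raise ValueError(f"{path}: not a spellbreak container (missing /meta)")
    v = int(f["meta"].attrs.get("format_version", -1))
    if v != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format version {v}")
    return str(f["meta"].attrs["paradigm"])


def write_session(path: str | Path, session, config_echo: str | None = None) -> None:
    extra = {} if config_echo is None else {"config_echo": config_echo}
    with h5py.File(path, "w") as f:
        if isinstance(session, synth.P300Session):
            _meta(
                f, "p300", fs=session.fs, split=session.split,
                n_repeats=session.n_repeats, **extra,
            )
            f.create_dataset("signal", data=session.signal)
            ev = np.array(
                [
                    (e.onset_sample, e.stimulus_id, e.repeat_index, e.trial_index)
                    for e in session.events
                ],
                dtype=np.int64,
            )
            f.create_dataset("events", data=ev)
            tr = np.array(
                [(t.trial_index, t.target_row, t.target_col) for t in session.trials],
                dtype=np.int64,
            )
            f.create_dataset("trials", data=tr)
            f.create_dataset(
                "trial_chars",
                data=np.array([t.target_char for t in session.trials], dtype="S1"),
            )
        elif isinstance(session, synth.SSVEPSession):
            _meta(f, "ssvep", fs=session.fs, **extra)
            for b, block in enumerate(session.blocks):
                for t, trial in enumerate(block):
                    d = f.create_dataset(f"blocks/{b}/trials/{t}/signal", data=trial.signal)
                    d.attrs["freq"] = trial.freq
                    d.attrs["char"] = trial.char
                    d.attrs["onset_sample"] = trial.onset_sample
        else:
            raise TypeError(f"unsupported session type {type(session).__name__}")


def read_session(path: str | Path):
    """Load a session container; invariants are re-validated on load."""
    with h5py.File(path, "r") as f:
        paradigm = _check_version(f, path)
        if paradigm == "p300":
            events = [synth.P300Event(*map(int, row)) for row in f["events"][()]]
            chars_arr = [c.decode() for c in f["trial_chars"][()]]
            trials = [
                synth.P300TrialInfo(int(r[0]), int(r[1]), int(r[2]), chars_arr[i])
                for i, r in enumerate(f["trials"][()])
            ]
            session = synth.P300Session(
                f["signal"][()],
                events,
                trials,
                float(f["meta"].attrs["fs"]),
                str(f["meta"].attrs["split"]),
                int(f["meta"].attrs["n_repeats"]),
            )
            session.validate()
            return session
        if paradigm == "ssvep":
            fs = float(f["meta"].attrs["fs"])
            blocks = []
            bg = f["blocks"]
            for b in sorted(bg, key=int):
                tg = bg[b]["trials"]
                block = []
                for t in sorted(tg, key=int):
                    d = tg[t]["signal"]
                    block.append(
                        synth.SSVEPTrial(
                            d[()], float(d.attrs["freq"]), str(d.attrs["char"]),
                            int(d.attrs["onset_sample"]), fs,
                        )
                    )
                blocks.append(block)
            session = synth.SSVEPSession(blocks, fs)
            session.validate()
            return session
        raise ValueError(f"{path}: unsupported paradigm {paradigm!r}")


# ---------------------------------------------------------------------------
# models and templates


def write_p300_model(
    path: str | Path, model: p300.P300VictimModel, provenance: str | None = None
) -> None:
    extra = {} if provenance is None else {"provenance": provenance}
    with h5py.File(path, "w") as f:
        _meta(f, "p300_model", fs=model.fs, shrinkage=model.config.shrinkage, **extra)
        f["meta"].attrs["config"] = json.dumps(
            {
                "n_xdawn": model.config.n_xdawn,
                "shrinkage": model.config.shrinkage,
                "mean_tol": model.config.mean_tol,
                "mean_max_iter": model.config.mean_max_iter,
                "logreg_c": model.config.logreg_c,
            }
        )
        f.create_dataset("w_target", data=model.filters.w_target)
        f.create_dataset("w_nontarget", data=model.filters.w_nontarget)
        f.create_dataset("evoked_target", data=model.filters.evoked_target)
        f.create_dataset("evoked_nontarget", data=model.filters.evoked_nontarget)
        f.create_dataset("c_ref", data=model.c_ref)
        f.create_dataset("coef", data=model.coef)
        f["meta"].attrs["intercept"] = model.intercept
        f["meta"].attrs["class_weight_0"] = model.class_weights[0]
        f["meta"].attrs["class_weight_1"] = model.class_weights[1]


def read_p300_model(path: str | Path) -> p300.P300VictimModel:
    with h5py.File(path, "r") as f:
        paradigm = _check_version(f, path)
        if paradigm != "p300_model":
            raise ValueError(f"{path}: expected a p300_model container, got {paradigm!r}")
        cfg = p300.P300ModelConfig(**json.loads(f["meta"].attrs["config"]))
        filters = p300.XdawnFilters(
            f["w_target"][()],
            f["w_nontarget"][()],
            f["evoked_target"][()],
            f["evoked_nontarget"][()],
        )
        return p300.P300VictimModel(
            config=cfg,
            filters=filters,
            c_ref=f["c_ref"][()],
            coef=f["coef"][()],
            intercept=float(f["meta"].attrs["intercept"]),
            class_weights={
                0: float(f["meta"].attrs["class_weight_0"]),
                1: float(f["meta"].attrs["class_weight_1"]),
            },
            fs=float(f["meta"].attrs["fs"]),
        )


def write_p300_template(
    path: str | Path, template: attack_p300.P300Template, provenance: str | None = None
) -> None:
    extra = {} if provenance is None else {"provenance": provenance}
    with h5py.File(path, "w") as f:
        _meta(
            f, "p300_template", fs=template.fs, kind=template.kind, **extra,
            epsilon=template.config.epsilon,
            band_lo=template.config.band[0], band_hi=template.config.band[1],
            filter_order=template.config.filter_order,
            template_len_ms=template.config.template_len_ms,
        )
        f.create_dataset("p", data=template.p)


def read_p300_template(path: str | Path) -> attack_p300.P300Template:
    with h5py.File(path, "r") as f:
        paradigm = _check_version(f, path)
        if paradigm != "p300_template":
            raise ValueError(f"{path}: expected a p300_template container")
        m = f["meta"].attrs
        cfg = attack_p300.P300AttackConfig(
            band=(float(m["band_lo"]), float(m["band_hi"])),
            filter_order=int(m["filter_order"]),
            template_len_ms=float(m["template_len_ms"]),
            epsilon=float(m["epsilon"]),
        )
        return attack_p300.P300Template(f["p"][()], float(m["fs"]), cfg, str(m["kind"]))


def write_ssvep_template(
    path: str | Path, template: attack_ssvep.SSVEPTemplate, provenance: str | None = None
) -> None:
    extra = {} if provenance is None else {"provenance": provenance}
    with h5py.File(path, "w") as f:
        _meta(
            f, "ssvep_template", **extra,
            attacker_freq=template.attacker_freq,
            converged=template.converged,
            n_iters=template.n_iters,
            train_spr_db=template.train_spr_db,
        )
        f.create_dataset("delta", data=template.delta)
        f.create_dataset("raw", data=template.raw)
        f.create_dataset("objective_log", data=template.objective_log)


def read_ssvep_template(path: str | Path) -> attack_ssvep.SSVEPTemplate:
    with h5py.File(path, "r") as f:
        paradigm = _check_version(f, path)
        if paradigm != "ssvep_template":
            raise ValueError(f"{path}: expected an ssvep_template container")
        m = f["meta"].attrs
        return attack_ssvep.SSVEPTemplate(
            delta=f["delta"][()],
            attacker_freq=float(m["attacker_freq"]),
            raw=f["raw"][()],
            converged=bool(m["converged"]),
            n_iters=int(m["n_iters"]),
            train_spr_db=float(m["train_spr_db"]),
            objective_log=f["objective_log"][()],
        )


# ---------------------------------------------------------------------------
# configuration files

_KNOWN_SECTIONS = {"p300_sim", "ssvep_sim", "p300_model", "p300_attack", "ssvep_attack", "seed"}


def load_config(path: str | Path) -> dict:
    """Strict YAML run configuration: unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return cfg
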