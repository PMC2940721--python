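"""Readers and writers for the package's plain-text formats.

FASTA for CRM sequences and ortholog alignments (via Biopython), PWM
blocks, TSV tables for TF roles and bin-aligned profiles, and a JSON
serialization of fitted model parameters.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import CRM, Dataset, ModelParams, TFSpec
from .motifs import PWM


def read_fasta(path) -> list:
    """[(name, sequence)] with names cut at the first whitespace."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_pwms(path, pwms) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.width}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("<\n")


def read_profiles(path) -> dict:
    """TSV with entity names in the first column -> name: (B,) array."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {str(name): row.to_numpy(dtype=float)
            for name, row in df.iterrows()}


def write_profiles(path, profiles: dict) -> None:
    df = pd.DataFrame({name: np.asarray(v) for name, v in profiles.items()}).T
    df.columns = [f"bin{j}" for j in range(df.shape[1])]
    df.to_csv(path, sep="\t", index_label="name")


def read_tf_info(path):
    """TF table -> (tf_specs, param seeds).

    Columns: name, role, optional binding_k / alpha / beta, optional
    coop_partners (comma-separated TF names).
    """
    df = pd.read_csv(path, sep="\t")
    specs = []
    binding_k, alpha, beta = {}, {}, {}
    for _, row in df.iterrows():
        partners = frozenset()
        if "coop_partners" in df.columns and isinstance(row.get("coop_partners"), str):
            partners = frozenset(p for p in row["coop_partners"].split(",") if p)
        specs.append(TFSpec(str(row["name"]), str(row["role"]), partners))
        for col, store in (("binding_k", binding_k), ("alpha", alpha),
                           ("beta", beta)):
            if col in df.columns and pd.notna(row.get(col)):
                store[str(row["name"])] = float(row[col])
    return specs, {"binding_k": binding_k, "alpha": alpha, "beta": beta}


def write_tf_info(path, tfs, params: ModelParams | None = None) -> None:
    rows = []
    for tf in tfs:
        row = {"name": tf.name, "role": tf.role,
               "coop_partners": ",".join(sorted(tf.coop_partners))}
        if params is not None:
            row["binding_k"] = params.binding_k.get(tf.name)
            row["alpha"] = params.alpha.get(tf.name)
            row["beta"] = params.beta.get(tf.name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def params_to_json(params: ModelParams) -> str:
    d = {"binding_k": params.binding_k, "alpha": params.alpha,
         "q_btm": params.q_btm,
         "omega": {"|".join(sorted(k)): v for k, v in params.omega.items()},
         "coop_range": params.coop_range, "beta": params.beta,
         "d_r": params.d_r,
         "n_ma": "inf" if params.n_ma == math.inf else int(params.n_ma),
         "mode": params.mode}
    return json.dumps(d, indent=2, sort_keys=True)


def params_from_json(text: str) -> ModelParams:
    d = json.loads(text)
    omega = {frozenset(k.split("|")): v for k, v in d.get("omega", {}).items()}
    n_ma = math.inf if d.get("n_ma", "inf") == "inf" else int(d["n_ma"])
    return ModelParams(binding_k=d["binding_k"], alpha=d["alpha"],
                       q_btm=d["q_btm"], omega=omega,
                       coop_range=d.get("coop_range", 50.0),
                       beta=d.get("beta", {}), d_r=d.get("d_r", 250.0),
                       n_ma=n_ma, mode=d.get("mode", "direct"))


def build_dataset(seqs, expr: dict, conc: dict, tfs, pwms: dict) -> Dataset:
    crms = []
    for name, seq in seqs:
        if name not in expr:
            raise KeyError(f"no expression profile for CRM {name!r}")
        crms.append(CRM(name=name, seq=seq, observed=expr[name]))
    return Dataset(crms=crms, tfs=tfs, conc=conc, pwms=pwms)


def save_dataset(outdir, dataset: Dataset) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "crms.fasta", [(c.name, c.seq) for c in dataset.crms])
    write_pwms(outdir / "pwms.txt", list(dataset.pwms.values()))
    write_tf_info(outdir / "tf_info.tsv", dataset.tfs)
    write_profiles(outdir / "tf_conc.tsv", dataset.conc)
    write_profiles(outdir / "expr.tsv",
                   {c.name: c.observed for c in dataset.crms})
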