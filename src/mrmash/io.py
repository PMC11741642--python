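"""Readers and writers for the package's on-disk formats.

Text formats are TSV with mandatory headers; matrices travel as ``.npy``
arrays with TSV/JSON sidecars for metadata so every artifact round-trips
across languages. Every pipeline stage writes a JSON manifest (config, seed,
input hashes, package version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .priors import MixturePrior
from .sumstats import GWASSummary, LDMatrix

__all__ = [
    "read_gwas_tsv", "write_gwas_tsv",
    "read_ld", "write_ld",
    "read_prior", "write_prior",
    "read_effects_tsv", "write_effects_tsv",
    "write_manifest", "file_sha256",
]


def write_gwas_tsv(
    gwas: GWASSummary,
    path: str | Path,
    chrom: Optional[np.ndarray] = None,
    pos_cm: Optional[np.ndarray] = None,
) -> None:
    """One row per variant: variant_id, chrom, pos_cm, n, beta_<ph>, se_<ph>.

    A per-phenotype ``n_<ph>`` column is added when sample sizes differ
    across phenotypes.
    """
    p = gwas.p
    df = pd.DataFrame({
        "variant_id": gwas.variant_ids,
        "chrom": np.array(["1"] * p) if chrom is None else np.asarray(chrom),
        "pos_cm": np.full(p, np.nan) if pos_cm is None else np.asarray(pos_cm),
    })
    npp = gwas.n_per_phenotype
    df["n"] = int(npp.max())
    if not np.all(npp == npp[0]):
        for t, ph in enumerate(gwas.phenotype_ids):
            df[f"n_{ph}"] = int(npp[t])
    for t, ph in enumerate(gwas.phenotype_ids):
        df[f"beta_{ph}"] = gwas.betahat[:, t]
        df[f"se_{ph}"] = gwas.se[:, t]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gwas_tsv(path: str | Path) -> GWASSummary:
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "n"):
        if col not in df.columns:
            raise ValueError(f"GWAS TSV {path} is missing required column {col!r}")
    phenos = [c[len("beta_"):] for c in df.columns if c.startswith("beta_")]
    if not phenos:
        raise ValueError(f"GWAS TSV {path} has no beta_<phenotype> columns")
    for ph in phenos:
        if f"se_{ph}" not in df.columns:
            raise ValueError(f"GWAS TSV {path} is missing column 'se_{ph}'")
    ids = df["variant_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"GWAS TSV {path} contains duplicated variant ids")
    betahat = df[[f"beta_{ph}" for ph in phenos]].to_numpy(float)
    se = df[[f"se_{ph}" for ph in phenos]].to_numpy(float)
    if np.any(~np.isfinite(se)):
        raise ValueError(f"GWAS TSV {path} has NaN or infinite standard errors")
    n_cols = [f"n_{ph}" for ph in phenos]
    if all(c in df.columns for c in n_cols):
        n = np.array([int(df[c].iloc[0]) for c in n_cols])
        if np.all(n == n[0]):
            n = int(n[0])
    else:
        n = int(df["n"].iloc[0])
    return GWASSummary(betahat=betahat, se=se, n=n, variant_ids=ids,
                       phenotype_ids=phenos)


def write_ld(ld: LDMatrix, dirpath: str | Path) -> None:
    """LD container: ld.npy + variants.tsv + structure.json in a directory."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "ld.npy", ld.R)
    pd.DataFrame({
        "variant_id": [f"v{j + 1}" for j in range(ld.p)],
        "chrom": ld.chrom,
        "pos_cm": ld.positions_cm,
    }).to_csv(d / "variants.tsv", sep="\t", index=False, float_format="%.17g")
    meta = {"structure": ld.structure}
    if ld.window_cm is not None:
        meta["window_cm"] = ld.window_cm
    if ld.blocks is not None:
        meta["blocks"] = [[int(a), int(b)] for a, b in ld.blocks]
    (d / "structure.json").write_text(json.dumps(meta, indent=1))


def read_ld(dirpath: str | Path) -> LDMatrix:
    d = Path(dirpath)
    R = np.load(d / "ld.npy")
    meta_df = pd.read_csv(d / "variants.tsv", sep="\t")
    meta = json.loads((d / "structure.json").read_text())
    blocks = meta.get("blocks")
    return LDMatrix(
        R=R,
        positions_cm=meta_df["pos_cm"].to_numpy(float),
        chrom=meta_df["chrom"].to_numpy(),
        structure=meta["structure"],
        window_cm=meta.get("window_cm"),
        blocks=[(a, b) for a, b in blocks] if blocks else None,
    )


def write_prior(prior: MixturePrior, path: str | Path) -> None:
    """Structured text: one '>label<TAB>weight' line per component followed
    by its r covariance rows (full float precision)."""
    lines = [f"r\t{prior.r}", f"K\t{prior.K}"]
    for k in range(prior.K):
        lines.append(f">{prior.labels[k]}\t{prior.w0[k]:.17g}")
        for row in prior.S0[k]:
            lines.append("\t".join(f"{v:.17g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_prior(path: str | Path) -> MixturePrior:
    lines = Path(path).read_text().strip().splitlines()
    try:
        r = int(lines[0].split("\t")[1])
        K = int(lines[1].split("\t")[1])
    except (IndexError, ValueError) as e:
        raise ValueError(f"malformed prior file header in {path}") from e
    labels, w0, S0 = [], [], []
    i = 2
    for _ in range(K):
        if not lines[i].startswith(">"):
            raise ValueError(f"malformed prior file {path} at line {i + 1}")
        lab, w = lines[i][1:].split("\t")
        labels.append(lab)
        w0.append(float(w))
        mat = [list(map(float, lines[i + 1 + a].split("\t"))) for a in range(r)]
        S0.append(np.array(mat))
        i += 1 + r
    return MixturePrior(w0=np.array(w0), S0=np.stack(S0), labels=labels)


def write_effects_tsv(
    B_bar: np.ndarray,
    variant_ids: list[str],
    phenotype_ids: list[str],
    path: str | Path,
) -> None:
    df = pd.DataFrame({"variant_id": variant_ids})
    for t, ph in enumerate(phenotype_ids):
        df[f"bbar_{ph}"] = B_bar[:, t]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_effects_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t")
    phenos = [c[len("bbar_"):] for c in df.columns if c.startswith("bbar_")]
    if "variant_id" not in df.columns or not phenos:
        raise ValueError(f"malformed effects TSV {path}")
    B = df[[f"bbar_{ph}" for ph in phenos]].to_numpy(float)
    return B, df["variant_id"].astype(str).tolist(), phenos


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    config: dict,
    seed: Optional[int],
    inputs: dict[str, str | Path],
) -> Path:
    """Reproducibility record written next to each stage's outputs."""
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_sha256": {
            name: file_sha256(p) for name, p in inputs.items() if Path(p).is_file()
        },
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path
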