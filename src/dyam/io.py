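"""On-disk interchange for cohorts, features and fitted models.

A simulated cohort directory contains::

    clinical.tsv          patient_id, response, pfs_months, pfs_event, tps
    lesion_features.tsv   patient_id, lesion_id, site, volume_cm3, f0..f{d-1}
    ihc_features.tsv      patient_id, f0..f{d-1}
    mutations.tsv         patient_id, gene, protein_change, alteration_type, oncogenic
    genomics.tsv          patient_id, <gene bits>, tmb
    manifest.json         files per patient (incl. rendered NIfTI / TIFF paths)

Rendered raw data (CT volume/mask NIfTI pairs, IHC TIFF image + PNG mask)
are optional and feed the featurization pipeline; the feature TSVs are the
authoritative patient-level representation and round-trip losslessly through
:func:`write_cohort` / :func:`read_cohort`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GENE_PANEL
from .records import Lesion, LesionBag, MultimodalRecord
from .model import DyAMClassifier
from .synthetic import generate_ihc_image, generate_lesion_volume, generate_mutation_table

__all__ = ["write_cohort", "read_cohort", "save_dyam", "load_dyam"]

PANEL_MB_DEFAULT = 1.5


def write_cohort(cohort, outdir, render: bool = False, panel_mb: float = PANEL_MB_DEFAULT) -> Path:
    """Write a cohort to ``outdir``; with ``render`` also emit raw images."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical, lesions, ihc_rows, gen_rows, mut_rows = [], [], [], [], []
    manifest: dict[str, dict] = {}
    for rec in cohort:
        entry: dict = {"files": {}}
        clinical.append({
            "patient_id": rec.patient_id, "response": rec.response,
            "pfs_months": rec.pfs_months, "pfs_event": rec.pfs_event,
            "tps": rec.tps if rec.tps is not None else "",
        })
        if rec.lesion_bag is not None:
            for j, les in enumerate(rec.lesion_bag):
                row = {"patient_id": rec.patient_id, "lesion_id": f"{rec.patient_id}_L{j}",
                       "site": les.site, "volume_cm3": les.volume_cm3}
                row.update({f"f{k}": v for k, v in enumerate(les.features)})
                lesions.append(row)
        if rec.ihc_features is not None:
            row = {"patient_id": rec.patient_id}
            row.update({f"f{k}": v for k, v in enumerate(rec.ihc_features)})
            ihc_rows.append(row)
        bits = rec.genomic_features[:-1].astype(int)
        grow = {"patient_id": rec.patient_id}
        grow.update({g: int(b) for g, b in zip(GENE_PANEL, bits)})
        grow["tmb"] = rec.tmb
        gen_rows.append(grow)
        genes_hit = {g for g, b in zip(GENE_PANEL, bits) if b}
        n_total = int(round(rec.tmb * panel_mb))
        table = generate_mutation_table(genes_hit, max(0, n_total - len(genes_hit)),
                                        panel_mb, seed=_stable_seed(rec.patient_id))
        for _, mrow in table.iterrows():
            mut_rows.append({"patient_id": rec.patient_id, **mrow.to_dict()})
        if render:
            entry["files"].update(_render_patient(rec, outdir))
        manifest[rec.patient_id] = entry

    pd.DataFrame(clinical).to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    pd.DataFrame(lesions).to_csv(outdir / "lesion_features.tsv", sep="\t", index=False)
    pd.DataFrame(ihc_rows).to_csv(outdir / "ihc_features.tsv", sep="\t", index=False)
    pd.DataFrame(gen_rows).to_csv(outdir / "genomics.tsv", sep="\t", index=False)
    pd.DataFrame(mut_rows).to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(
        {"panel_mb": panel_mb, "patients": manifest}, indent=1))
    return outdir


def _stable_seed(patient_id: str) -> int:
    import zlib

    return zlib.crc32(patient_id.encode()) % (2**31)


def _render_patient(rec: MultimodalRecord, outdir: Path) -> dict:
    import imageio.v3 as iio
    import nibabel as nib
    import tifffile

    files: dict = {}
    if rec.lesion_bag is not None:
        ct_dir = outdir / "ct"
        ct_dir.mkdir(exist_ok=True)
        files["lesions"] = []
        for j, les in enumerate(rec.lesion_bag):
            vol, mask = generate_lesion_volume(les.site, seed=_stable_seed(f"{rec.patient_id}_L{j}"))
            vpath = ct_dir / f"{rec.patient_id}_L{j}_vol.nii.gz"
            mpath = ct_dir / f"{rec.patient_id}_L{j}_mask.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), vpath)
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), mpath)
            files["lesions"].append({"site": les.site, "volume": vpath.name, "mask": mpath.name})
    if rec.tps is not None:
        ihc_dir = outdir / "ihc"
        ihc_dir.mkdir(exist_ok=True)
        img, mask = generate_ihc_image(rec.tps, seed=_stable_seed(f"{rec.patient_id}_ihc"))
        ipath = ihc_dir / f"{rec.patient_id}.tiff"
        mpath = ihc_dir / f"{rec.patient_id}_mask.png"
        tifffile.imwrite(ipath, (img * 255).astype(np.uint8))
        iio.imwrite(mpath, (mask.astype(np.uint8) * 255))
        files["ihc"] = {"image": f"ihc/{ipath.name}", "mask": f"ihc/{mpath.name}"}
    return files


def read_cohort(indir) -> list[MultimodalRecord]:
    """Reconstruct patient records from a cohort directory."""
    indir = Path(indir)
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t")
    lesions = pd.read_csv(indir / "lesion_features.tsv", sep="\t")
    ihc = pd.read_csv(indir / "ihc_features.tsv", sep="\t")
    genomics = pd.read_csv(indir / "genomics.tsv", sep="\t")
    les_by_pat = dict(tuple(lesions.groupby("patient_id"))) if len(lesions) else {}
    ihc_by_pat = ihc.set_index("patient_id") if len(ihc) else pd.DataFrame()
    gen_by_pat = genomics.set_index("patient_id")
    feat_cols = sorted((c for c in lesions.columns if c.startswith("f")),
                       key=lambda c: int(c[1:])) if len(lesions) else []
    ihc_cols = sorted((c for c in ihc.columns if c.startswith("f")),
                      key=lambda c: int(c[1:])) if len(ihc) else []
    records = []
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        bag = None
        if pid in les_by_pat:
            ls = [Lesion(site=r["site"], features=r[feat_cols].to_numpy(dtype=float),
                         volume_cm3=float(r["volume_cm3"]))
                  for _, r in les_by_pat[pid].iterrows()]
            bag = LesionBag(lesions=ls)
        tps = None if pd.isna(row["tps"]) or row["tps"] == "" else float(row["tps"])
        feats = None
        if tps is not None and len(ihc_by_pat) and pid in ihc_by_pat.index:
            feats = ihc_by_pat.loc[pid, ihc_cols].to_numpy(dtype=float)
        g = gen_by_pat.loc[pid]
        genomic = np.concatenate([[float(g[gene]) for gene in GENE_PANEL], [float(g["tmb"])]])
        records.append(MultimodalRecord(
            patient_id=pid, response=int(row["response"]), pfs_months=float(row["pfs_months"]),
            pfs_event=int(row["pfs_event"]), lesion_bag=bag, ihc_features=feats, tps=tps,
            genomic_features=genomic))
    return records


def save_dyam(model: DyAMClassifier, path) -> None:
    """Serialize a fitted fusion model (weights, scalers, config) to JSON."""
    payload = {
        "config": model.get_params(),
        "modality_names": model.modality_names_,
        "heads": [{k: np.asarray(v).tolist() for k, v in head.items()} for head in model.heads_],
        "means": [m.tolist() for m in model.means_],
        "scales": [s.tolist() for s in model.scales_],
    }
    payload["config"].pop("modality_names", None)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_dyam(path) -> DyAMClassifier:
    payload = json.loads(Path(path).read_text())
    model = DyAMClassifier(modality_names=payload["modality_names"], **payload["config"])
    model.modality_names_ = payload["modality_names"]
    model.heads_ = [{k: np.asarray(v) for k, v in head.items()} for head in payload["heads"]]
    model.means_ = [np.asarray(m) for m in payload["means"]]
    model.scales_ = [np.asarray(s) for s in payload["scales"]]
    model.classes_ = np.array([0, 1])
    model.n_modalities_ = len(model.heads_)
    return model
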