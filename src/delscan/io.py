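"""File-format readers and writers.

External conventions are converted at the boundary: bedGraph and BED are
0-based half-open and pass through unchanged; GFF3 is 1-based closed and is
converted to 0-based half-open on reading.  No internal operation ever sees
1-based coordinates.  All writers produce plain TSV that the corresponding
reader round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import DeletionCall, GeneModel
from .coverage import BinnedCoverage, NormalizedCoverage, PartsMap, ReadPlacement


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#") or stripped.startswith("track"):
                continue
            yield lineno, stripped


def read_coverage(path, dialect: str = "bedGraph", line_id: str | None = None,
                  bin_size: int = 1_000_000):
    """Read per-bin counts (bedGraph) or raw read placements (placements_tsv).

    bedGraph: chrom, start, end, count (0-based half-open); header/comment
    and ``track`` lines are skipped; intervals within a chromosome must be
    non-overlapping.  placements_tsv: chrom, pos, mapq, flag_ok — returns a
    list of ReadPlacement instead of binned coverage.
    """
    path = Path(path)
    if dialect == "placements_tsv":
        placements = []
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                placements.append(
                    ReadPlacement(
                        chromosome=fields[0],
                        position=int(fields[1]),
                        mapq=int(fields[2]),
                        proper_pair_and_primary=fields[3] in ("1", "True", "true"),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return placements
    if dialect != "bedGraph":
        raise ValueError(f"unknown dialect {dialect!r}")

    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        try:
            chrom, start, end, count = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
        if count < 0:
            raise ValueError(f"{path}:{lineno}: negative count {count}")
        if end <= start:
            raise ValueError(f"{path}:{lineno}: empty interval [{start}, {end})")
        rows.append((chrom, start, end, count))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
    return BinnedCoverage(
        line_id=line_id or path.stem, bin_size=bin_size, df=df
    )


def write_coverage(cov: BinnedCoverage, path) -> None:
    """Write binned counts as 4-column bedGraph."""
    cov.df[["chrom", "start", "end", "count"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_normalized(norm: NormalizedCoverage, cov: BinnedCoverage | None, path) -> None:
    """Per-bin TSV: line_id, chrom, start, end, count, normalized_value, masked."""
    out = norm.df[["chrom", "start", "end"]].copy()
    out.insert(0, "line_id", norm.line_id)
    out["count"] = cov.df["count"].to_numpy() if cov is not None else -1
    value = norm.df["value"].to_numpy()
    masked = np.isnan(value)
    out["normalized_value"] = np.where(masked, 0.0, value).round(6)
    out["masked"] = np.where(masked, 1, 0)
    out.to_csv(path, sep="\t", index=False)


def read_normalized(path) -> NormalizedCoverage:
    df = pd.read_csv(path, sep="\t")
    value = df["normalized_value"].to_numpy(dtype=float)
    value[df["masked"].to_numpy() == 1] = np.nan
    out = df[["chrom", "start", "end"]].copy()
    out["value"] = value
    bin_size = int((df["end"] - df["start"]).max())
    return NormalizedCoverage(
        line_id=str(df["line_id"].iloc[0]),
        reference_line_id="",
        bin_size=bin_size,
        df=out,
    )


def read_parts_map(path) -> PartsMap:
    """TSV with columns part1_id, part2_id, full_id, part1_length."""
    df = pd.read_csv(path, sep="\t")
    required = {"part1_id", "part2_id", "full_id", "part1_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return PartsMap(df[["part1_id", "part2_id", "full_id", "part1_length"]])


def write_parts_map(parts: PartsMap, path) -> None:
    parts.df.to_csv(path, sep="\t", index=False)


def write_calls(calls, path) -> None:
    """Deletion-call TSV mirroring the reported table columns."""
    from .calling import calls_to_frame

    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[DeletionCall]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        flags = set() if pd.isna(row.get("flags")) or not row.get("flags") else set(
            str(row["flags"]).split(";")
        )
        out.append(
            DeletionCall(
                line_id=str(row["line_id"]),
                chromosome=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                n_low_bins=int(row["n_low_bins"]),
                method=str(row["method"]),
                flags=flags,
            )
        )
    return out


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA features) or BED6.

    GFF3 1-based closed coordinates become 0-based half-open.  Confidence is
    read from a ``confidence`` attribute when present (else ``high``); a file
    mixing the two formats is rejected.
    """
    path = Path(path)
    gff_rows, bed_rows = [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 9 and fields[3].isdigit() and fields[4].isdigit():
            gff_rows.append((lineno, fields))
        elif len(fields) in (3, 6) and fields[1].lstrip("-").isdigit():
            bed_rows.append((lineno, fields))
        else:
            raise ValueError(f"{path}:{lineno}: unrecognized gene-model line")
    if gff_rows and bed_rows:
        raise ValueError(f"{path}: mixed GFF3 and BED content")

    genes: list[GeneModel] = []
    if gff_rows:
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        feature_types = set(db.featuretypes())
        wanted = "gene" if "gene" in feature_types else "mRNA"
        for feat in db.features_of_type(wanted, order_by="start"):
            if feat.end < feat.start:
                raise ValueError(f"{path}: gene {feat.id}: end < start")
            confidence = feat.attributes.get("confidence", ["high"])[0]
            genes.append(
                GeneModel(
                    gene_id=feat.id,
                    chromosome=feat.seqid,
                    start=feat.start - 1,  # 1-based closed -> 0-based half-open
                    end=feat.end,
                    confidence=confidence,
                )
            )
        return genes

    for lineno, fields in bed_rows:
        start, end = int(fields[1]), int(fields[2])
        if end < start:
            raise ValueError(f"{path}:{lineno}: end < start")
        name = fields[3] if len(fields) >= 4 else f"gene{lineno}"
        genes.append(GeneModel(gene_id=name, chromosome=fields[0], start=start, end=end))
    return genes


def write_gene_models(genes, path) -> None:
    """Write gene models as BED6."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t+\n")


def read_marker_panel(path):
    """TSV: marker_id, genome, arm, order_index[, position]."""
    from .genotyping import Marker

    df = pd.read_csv(path, sep="\t")
    return [
        Marker(
            marker_id=str(r["marker_id"]),
            genome_specificity=str(r["genome"]),
            chromosome_arm=str(r["arm"]),
            order_index=int(r["order_index"]),
            position=int(r["position"]) if "position" in df.columns and pd.notna(r["position"]) else None,
        )
        for _, r in df.iterrows()
    ]


def read_marker_observations(path):
    """TSV: plant_id, marker_id, call."""
    from .genotyping import MarkerObservation

    df = pd.read_csv(path, sep="\t")
    return [
        MarkerObservation(
            plant_id=str(r["plant_id"]), marker_id=str(r["marker_id"]), call=str(r["call"])
        )
        for _, r in df.iterrows()
    ]


def write_marker_observations(observations, path) -> None:
    pd.DataFrame(
        {
            "plant_id": [o.plant_id for o in observations],
            "marker_id": [o.marker_id for o in observations],
            "call": [o.call for o in observations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_image(path, scale: float, image_id: str | None = None):
    """Load a grayscale TIFF/PNG micrograph with its µm-per-pixel scale."""
    import imageio.v3 as iio

    from .granules import Micrograph

    pixels = iio.imread(path)
    if pixels.ndim == 3:  # collapse RGB to luminance
        pixels = pixels[..., :3].mean(axis=2)
    return Micrograph(pixels=pixels, scale=scale, image_id=image_id or Path(path).stem)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
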