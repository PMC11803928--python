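"""VCF 4.2 reading (cyvcf2/htslib) and writing (plain text).

Reading keeps multi-allelic records (flagged through ``GenotypeMatrix.n_alt``)
and maps any genotype containing a missing allele to a missing dosage.
Writing emits one record per site with FORMAT ``GT:DP:GQ`` when depth and
quality fields are present, ``GT`` otherwise; output is deterministic given
the matrix, so seeded simulations round-trip byte-identically.
"""

from __future__ import annotations

import numpy as np
from cyvcf2 import VCF

from .core import GenotypeMatrix, MISSING

_INT_SENTINEL = -2147483648


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into the dosage model.

    Raises ``ValueError`` naming the record number for malformed or
    unsorted input.
    """
    reader = VCF(str(path), gts012=False)
    samples = np.array(reader.samples, dtype=object)
    has_dp = "DP" in [f["ID"] for f in _format_ids(reader)]
    has_gq = "GQ" in [f["ID"] for f in _format_ids(reader)]

    chrom, pos, ref, alt = [], [], [], []
    dos_rows, dp_rows, gq_rows = [], [], []
    last: dict[str, int] = {}
    order: list[str] = []

    record_no = 0
    try:
        for v in reader:
            record_no += 1
            c = str(v.CHROM)
            if c not in last:
                if c in order:
                    raise ValueError(f"record {record_no}: chromosome {c} out of order (input unsorted)")
                order.append(c)
                last[c] = -1
            elif order[-1] != c:
                raise ValueError(f"record {record_no}: chromosome {c} out of order (input unsorted)")
            if v.POS <= last[c]:
                raise ValueError(
                    f"record {record_no}: position {v.POS} on chromosome {c} "
                    f"not strictly increasing (input unsorted)"
                )
            last[c] = v.POS

            chrom.append(c)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(",".join(v.ALT) if v.ALT else ".")

            g = np.array([row[:2] for row in v.genotypes], dtype=np.int32)
            miss = (g < 0).any(axis=1)
            d = np.where(miss, MISSING, (g > 0).sum(axis=1))
            dos_rows.append(d.astype(np.int8))

            if has_dp:
                dp = v.format("DP")
                dp_rows.append(_clean_int(dp, len(samples)))
            if has_gq:
                gq = v.format("GQ")
                gq_rows.append(_clean_int(gq, len(samples)))
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"malformed VCF record {record_no + 1} in {path}: {exc}") from exc

    m = len(pos)
    n = len(samples)
    dosage = np.stack(dos_rows, axis=1) if m else np.zeros((n, 0), dtype=np.int8)
    dp = np.stack(dp_rows, axis=1) if (has_dp and m) else (np.zeros((n, 0), np.int16) if has_dp else None)
    gq = np.stack(gq_rows, axis=1) if (has_gq and m) else (np.zeros((n, 0), np.int16) if has_gq else None)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
        dp=dp,
        gq=gq,
        metadata={"source": str(path)},
    )


def _format_ids(reader):
    for h in reader.header_iter():
        info = h.info()
        if info.get("HeaderType") == "FORMAT":
            yield info


def _clean_int(arr, n) -> np.ndarray:
    if arr is None:
        return np.full(n, -1, dtype=np.int16)
    out = np.asarray(arr).reshape(n, -1)[:, 0].astype(np.int64)
    out[out == _INT_SENTINEL] = -1
    return np.clip(out, -1, 32000).astype(np.int16)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as sorted VCF 4.2 text, one ALT per record."""
    with_fmt = gm.dp is not None and gm.gq is not None
    lengths = gm.metadata.get("chrom_lengths", {})
    lines = ["##fileformat=VCFv4.2", "##source=fawpop"]
    for c in dict.fromkeys(gm.chrom):
        if c in lengths:
            lines.append(f"##contig=<ID={c},length={lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_fmt:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header_cols + list(gm.samples)))

    fmt = "GT:DP:GQ" if with_fmt else "GT"
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j in range(gm.n_sites):
            cols = [gm.chrom[j], str(gm.pos[j]), ".", gm.ref[j], gm.alt[j], ".", "PASS", ".", fmt]
            d = gm.dosage[:, j]
            if with_fmt:
                dpj, gqj = gm.dp[:, j], gm.gq[:, j]
                cols.extend(f"{_GT[int(d[i])]}:{int(dpj[i])}:{int(gqj[i])}" for i in range(gm.n_samples))
            else:
                cols.extend(_GT[int(di)] for di in d)
            fh.write("\t".join(cols) + "\n")
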