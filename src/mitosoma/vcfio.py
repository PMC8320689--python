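"""VCF emission for call tables (contig chrM, rCRS length)."""

from __future__ import annotations

import pandas as pd

from mitosoma import __version__
from mitosoma.reference import MT_LENGTH

_HEADER = """\
##fileformat=VCFv4.2
##source=mitosoma {version}
##contig=<ID=chrM,length={length}>
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=low_cov,Description="Depth below minimum coverage">
##FILTER=<ID=low_vaf,Description="Variant allele frequency below minimum">
##FILTER=<ID=strand_bias,Description="Failed the strand-bias filter">
##FILTER=<ID=fdr_fail,Description="Benjamini-Hochberg q-value above alpha">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Quality-weighted variant allele frequency (heteroplasmy)">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=ADF,Number=1,Type=Integer,Description="Alternate reads, forward strand">
##INFO=<ID=ADR,Number=1,Type=Integer,Description="Alternate reads, reverse strand">
##INFO=<ID=PQ,Number=1,Type=Float,Description="Site-test p-value">
##INFO=<ID=QQ,Number=1,Type=Float,Description="BH-adjusted q-value">
{somatic_line}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_SOMATIC_INFO = '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Tumor-only mutation">\n'


def allele_to_vcf(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Convert a caller allele spec to VCF POS/REF/ALT (left-anchored)."""
    if alt.startswith("+"):
        return position, ref, ref + alt[1:]
    if alt.startswith("-"):
        return position, ref + alt[1:], ref
    return position, ref, alt


def write_vcf(calls: pd.DataFrame, path, somatic: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(
            _HEADER.format(
                version=__version__,
                length=MT_LENGTH,
                somatic_line=_SOMATIC_INFO if somatic else "",
            )
        )
        for r in calls.itertuples():
            pos, ref, alt = allele_to_vcf(int(r.position), str(r.ref), str(r.alt))
            filt = str(r.filters).replace(",", ";") if hasattr(r, "filters") else "PASS"
            info = (
                f"VAF={r.vaf:.6f};DP={int(r.depth)};ADF={int(r.alt_fwd)};"
                f"ADR={int(r.alt_rev)};PQ={r.p_value:.3e};QQ={r.q_value:.3e}"
            )
            if somatic:
                info += ";SOMATIC"
            fh.write(f"chrM\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n")
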