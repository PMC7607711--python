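"""APOE-e4 diplotype calling from rs429358 and rs7412.

The three common APOE protein isoforms are encoded by a two-SNP haplotype:

=========  ==========  ========
isoform    rs429358    rs7412
=========  ==========  ========
e2         T           T
e3         T           C
e4         C           C
(e1)       C           T
=========  ==========  ========

An individual's diplotype is the unordered pair of isoform alleles. From
unphased genotypes at the two sites the diplotype is uniquely determined
except for the double heterozygote (C/T at both), which is consistent with
either e2/e4 or e1/e3; following standard practice the very rare e1 is
assumed absent and the call is e2/e4. Genotype pairs that force an e1
haplotype in every phasing (e.g. rs429358 C/C with rs7412 C/T) cannot be
expressed in the six common categories and are flagged as no-calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ApoeCall",
    "DIPLOTYPES",
    "call_diplotype",
    "call_from_dosages",
    "call_cohort",
    "e4_indicator_frame",
]

#: The six common diplotype categories, in conventional order.
DIPLOTYPES = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")

# (rs429358 allele, rs7412 allele) -> isoform
_HAPLOTYPE_ISOFORM = {
    ("C", "C"): "e4",
    ("T", "C"): "e3",
    ("T", "T"): "e2",
    ("C", "T"): "e1",
}

_E4_RANK = {"e1": 0, "e2": 1, "e3": 2, "e4": 3}


@dataclass(frozen=True)
class ApoeCall:
    """A per-individual APOE diplotype call with e4 copy-number indicators.

    ``flag`` is ``"ok"`` for a clean call; no-calls carry a reason and a
    ``None`` diplotype with zeroed indicators (they are excluded from
    analysis, not coerced to a category).
    """

    individual_id: str
    diplotype: str | None
    e4_count: int
    one_e4: int
    two_e4: int
    flag: str = "ok"

    def __post_init__(self) -> None:
        if self.diplotype is not None:
            expected = self.diplotype.count("e4")
            if expected != self.e4_count:
                raise ValidationError(
                    f"{self.individual_id}: e4_count {self.e4_count} inconsistent "
                    f"with diplotype {self.diplotype}"
                )
        if self.one_e4 and self.two_e4:
            raise ValidationError("one_e4 and two_e4 cannot both be set")
        if (self.one_e4, self.two_e4) != (
            int(self.e4_count == 1),
            int(self.e4_count == 2),
        ):
            raise ValidationError("e4 indicators inconsistent with e4_count")


def _no_call(individual_id: str, reason: str) -> ApoeCall:
    return ApoeCall(individual_id, None, 0, 0, 0, flag=reason)


def call_diplotype(
    g429358: str, g7412: str, individual_id: str = ""
) -> ApoeCall:
    """Call the diplotype from unphased two-allele genotypes.

    ``g429358`` and ``g7412`` are two-character strings over {C, T}
    (order irrelevant), e.g. ``"CT"``. Missing or non-{C,T} alleles yield
    a flagged no-call rather than an exception so that cohort-scale
    calling can proceed.
    """
    a = sorted(str(g429358).upper())
    b = sorted(str(g7412).upper())
    if len(a) != 2 or len(b) != 2 or not set(a) <= {"C", "T"} or not set(b) <= {"C", "T"}:
        return _no_call(individual_id, "invalid_genotype")
    # Two possible phasings of the unphased pair of genotypes.
    phasings = [
        ((a[0], b[0]), (a[1], b[1])),
        ((a[0], b[1]), (a[1], b[0])),
    ]
    candidates = set()
    for h1, h2 in phasings:
        iso = tuple(sorted((_HAPLOTYPE_ISOFORM[h1], _HAPLOTYPE_ISOFORM[h2]),
                           key=_E4_RANK.get))
        candidates.add(iso)
    # Prefer any phasing avoiding e1; the double heterozygote offers both
    # e2/e4 and e1/e3 and resolves to e2/e4 (e1 treated as absent).
    viable = [c for c in candidates if "e1" not in c]
    if not viable:
        return _no_call(individual_id, "e1_haplotype")
    iso = viable[0] if len(viable) == 1 else ("e2", "e4")
    e4_count = sum(1 for x in iso if x == "e4")
    return ApoeCall(
        individual_id=individual_id,
        diplotype=f"{iso[0]}/{iso[1]}",
        e4_count=e4_count,
        one_e4=int(e4_count == 1),
        two_e4=int(e4_count == 2),
    )


def call_from_dosages(
    d429358: float,
    d7412: float,
    band: float = 0.1,
    counted_alleles: tuple[str, str] = ("C", "C"),
    individual_id: str = "",
) -> ApoeCall:
    """Hard-call fractional dosages at the two sites, then call the diplotype.

    A dosage within ``band`` of an integer k is hard-called as k copies of
    that site's counted allele (the remaining 2-k copies are the other of
    {C, T}); dosages outside every band produce a flagged no-call. The
    default band of +/-0.1 suits near-deterministic imputation (the two
    sites are typically imputed at INFO ~0.99).
    """
    genotypes = []
    for d, counted in zip((d429358, d7412), counted_alleles):
        if counted not in ("C", "T"):
            return _no_call(individual_id, "invalid_counted_allele")
        other = "T" if counted == "C" else "C"
        if d is None or not np.isfinite(d):
            return _no_call(individual_id, "missing_dosage")
        k = int(round(d))
        if k < 0 or k > 2 or abs(d - k) > band:
            return _no_call(individual_id, "out_of_band_dosage")
        genotypes.append(counted * k + other * (2 - k))
    return call_diplotype(genotypes[0], genotypes[1], individual_id=individual_id)


def call_cohort(
    geno: GenotypeMatrix,
    rs429358: str = "rs429358",
    rs7412: str = "rs7412",
    band: float = 0.1,
) -> pd.DataFrame:
    """Call APOE diplotypes for every individual in a genotype matrix.

    The two variant IDs must be present with counted_allele annotations in
    {C, T}. Returns a DataFrame with columns individual_id, diplotype,
    e4_count, one_e4, two_e4, call_flag.
    """
    vidx = geno.variant_index()
    for rsid in (rs429358, rs7412):
        if rsid not in vidx.index:
            raise ValidationError(f"variant {rsid} not present in genotype matrix")
    c1 = int(vidx[rs429358])
    c2 = int(vidx[rs7412])
    counted = (
        str(geno.variants.loc[c1, "counted_allele"]).upper(),
        str(geno.variants.loc[c2, "counted_allele"]).upper(),
    )
    rows = []
    for i, iid in enumerate(geno.individual_ids):
        call = call_from_dosages(
            geno.dosages[i, c1],
            geno.dosages[i, c2],
            band=band,
            counted_alleles=counted,
            individual_id=iid,
        )
        rows.append(
            {
                "individual_id": call.individual_id,
                "diplotype": call.diplotype,
                "e4_count": call.e4_count,
                "one_e4": call.one_e4,
                "two_e4": call.two_e4,
                "call_flag": call.flag,
            }
        )
    out = pd.DataFrame(rows)
    n_nocall = int((out["call_flag"] != "ok").sum())
    if n_nocall:
        logger.info("call_cohort: %d of %d individuals flagged no-call",
                    n_nocall, len(out))
    return out


def e4_indicator_frame(calls: pd.DataFrame) -> pd.DataFrame:
    """Indexable one_e4/two_e4 indicators for clean calls only."""
    ok = calls[calls["call_flag"] == "ok"]
    return ok.set_index("individual_id")[["one_e4", "two_e4"]]
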