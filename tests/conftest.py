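import pytest

from carrierscreen.types import (
    Consequence,
    GeneSpec,
    Loftee,
    Moi,
    PolyPhen,
    Sift,
    Source,
    VariantRecord,
)


def make_variant(
    variant_id="v1",
    gene="GENE001",
    consequence=Consequence.MISSENSE,
    cadd_phred=25.0,
    sift=Sift.DAMAGING,
    polyphen=PolyPhen.PROBABLY_DAMAGING,
    loftee=Loftee.NOT_APPLICABLE,
    maf=0.001,
    source=Source.GNOMAD,
    **kw,
):
    return VariantRecord(
        variant_id=variant_id,
        chrom=kw.pop("chrom", "1"),
        pos=kw.pop("pos", 100),
        ref=kw.pop("ref", "A"),
        alt=kw.pop("alt", "G"),
        gene=gene,
        consequence=consequence,
        cadd_phred=cadd_phred,
        sift=sift,
        polyphen=polyphen,
        loftee=loftee,
        maf=maf,
        source=source,
        **kw,
    )


@pytest.fixture
def small_panel():
    return [
        GeneSpec("GENE001", Moi.DOMINANT, nhs_panel=True),
        GeneSpec("GENE002", Moi.RECESSIVE, nhs_panel=True),
        GeneSpec("GENE003", Moi.DOMINANT, nhs_panel=False),
        GeneSpec("GENE004", Moi.RECESSIVE, nhs_panel=False),
    ]
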