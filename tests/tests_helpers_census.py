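"""Shared helper for building minimal census tables in tests."""

from wrkycensus.records import CensusRow


def make_rows(groups):
    rows = []
    for i, group in enumerate(groups, start=1):
        rows.append(
            CensusRow(
                gene_name=f"WRKY{i}",
                locus_id=f"g{i}",
                chromosome="Chr01",
                start=i * 1000,
                end=i * 1000 + 500,
                pi=6.0,
                mw_kda=40.0,
                heptapeptide="WRKYGQK",
                zinc_finger="C2HC" if group == "III" else "C2H2",
                domain_count=2 if group == "I" else 1,
                group=group,
                length_aa=300,
            )
        )
    return rows
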