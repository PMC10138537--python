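"""Shared test utilities."""


def truth_binaries(panel, sites):
    """Ground-truth binary vectors of a panel's alleles over found sites."""
    out = []
    for allele in panel.alleles:
        bits = []
        for site in sites.sites:
            base = allele[site.column - 1]
            assert base in (site.major, site.minor)
            bits.append("1" if base == site.major else "0")
        out.append("".join(bits))
    return out
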