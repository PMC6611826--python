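>TPD52_HUMAN_184aa_synthetic reconstruction of the 184-aa human tumor protein D52 isoform, written offline from memory; residues ~94-140 are uncertain — verify against the database record before use
MDSAGQDINLNSPNKGLLSDSMTDVPVDTGVAARTPAVEGLSELEEEELRAELAKVEEEI
VTLRQVLAAKERHCGELKRKLGLSTLGGLKQNLSRSWHDVQVSSAYVKTSEKLGEWNEKV
TQSDLYKKTQETLSQAGQKTSAALSTVGSAISRKLGDMRNSATFKSFEDRVGTIKSKVVG
DREN
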