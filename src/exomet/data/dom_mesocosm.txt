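# Mesocosm phytoplankton-bloom DOM formula set, reconstructed from the
# per-metabolite mesocosm presence flags of the packaged metabolite table
# (the underlying FT-ICR-MS spectra are not publicly deposited).
# One Hill-notation molecular formula per line.
C8H9NO3
C14H18N2O4
C14H14N2O6
C11H11NO2
C11H12N2O2
C12H19NO4
C10H15NO4
C8H13NO4
C10H14N2O4
C9H11NO3
C10H13NO5
C9H8O4
C9H11NO2
C7H10O4
C7H9NO4
C6H11NO4
C17H18N2O6
C9H11NO4
C10H14N2O5
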