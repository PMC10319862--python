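"""Simulate a DIA run and build the DDA inclusion list from it.

The precursor-analysis step predicts a retention window for every sum
composition from the palmitic/stearic anchors, finds precursor peaks in
the DIA chromatograms, and resamples the observations onto a 0.3 s target
grid so that even trace precursors keep enough MS/MS points per peak.
"""

from ozfad.chem import builtin_agents
from ozfad.config import PipelineConfig
from ozfad.discovery import build_target_list, find_precursors
from ozfad.simulate import InstrumentModel, plasma_like_mixture, simulate_dia

agent = builtin_agents()["AMPP"]
config = PipelineConfig()
mixture = plasma_like_mixture()
instrument = InstrumentModel()

run = simulate_dia(mixture, instrument, agent, seed=4)
observations = find_precursors(run, agent, config)
targets = build_target_list(observations, config)

print(f"{len(observations)} precursor features over a {instrument.gradient_min:g}-min gradient")
for o in observations:
    print(f"  FA {o.carbons}:{o.n_double_bonds}  rt {o.apex_rt:6.3f} min  "
          f"area {o.abundance:10.0f}  mass error {o.ppm_error:+.1f} ppm")
print(f"{len(targets)} inclusion-list slots of {targets.slot_width_s} s "
      f"(= gradient / slot width); each detected precursor keeps at least "
      f"{config.min_points_per_peak} slots where its peak allows.")
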