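"""Quality control and the seven single-neuron features.

Each unit passes four QC rules (firing rate, refractory violations,
waveform shape, ACG-fit quality) and is then summarized by four waveform
features (durations in ms, the dimensionless AB ratio) and three firing-
pattern features (burstiness in [0,1], ACG time constants in ms).
"""

from fcpredict.features import qc_and_featurize
from fcpredict.synth import generate_study
from fcpredict.types import FEATURE_NAMES, PlantedResponseModel

study = generate_study(
    n_chips=2, networks_per_chip=1, n_neurons=(25, 30), duration=600.0,
    response_model=PlantedResponseModel(), seed=3,
)
nw = study.networks[0]

features, report = qc_and_featurize(list(zip(nw.recordings[0], nw.footprints)))

print("QC report:", report.as_dict())
print(f"\nfirst surviving unit (id {features[0].unit_id}):")
for name, value in features[0].as_dict().items():
    print(f"  {name:>15s} = {value:8.3f}")
print("\nDurations are in ms; burstiness is the fraction of inter-spike")
print("intervals shorter than 6 ms; tau_rise/tau_decay describe how the")
print("autocorrelogram rises and relaxes around short lags.")
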