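# Sensor inventory of the default simulated household.
sensors:
  - {sensor_id: bed, kind: binary_state}
  - {sensor_id: chair, kind: binary_state}
  - {sensor_id: toilet, kind: impulsive}
  - {sensor_id: fridge, kind: impulsive}
  - {sensor_id: door, kind: impulsive}
  - {sensor_id: pir, kind: impulsive}
  - {sensor_id: tv, kind: real_valued, binarize_threshold: 40.0}
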