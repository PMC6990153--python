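# Default voltage-clamp protocol definitions.
#
# These grids are count-consistent reconstructions: sweep counts, varying
# elements and total durations satisfy every published constraint on the
# originals (6/7/16/9 sweeps for Pr2-5, 228 s combined for Pr2-5, 8 s for
# Pr7), while the exact voltage/duration values are package defaults that
# can be overridden here without touching code.
#
# Times in milliseconds, voltages in millivolts.

dt: 0.1

pr2:
  holding: {voltage: -80.0, duration: 1000.0}
  p1_voltage: 40.0
  p1_durations: [100.0, 200.0, 500.0, 1000.0, 2000.0, 5500.0]
  tail: {voltage: -40.0, duration: 1000.0}
  final: {voltage: -80.0, duration: 500.0}

pr3:
  holding: {voltage: -80.0, duration: 1000.0}
  p1_voltages: [-60.0, -40.0, -20.0, 0.0, 20.0, 40.0, 60.0]
  p1_duration: 6000.0
  tail: {voltage: -40.0, duration: 1500.0}
  final: {voltage: -80.0, duration: 500.0}

pr4:
  holding: {voltage: -80.0, duration: 500.0}
  p1: {voltage: 40.0, duration: 1500.0}
  p2: {voltage: -90.0, duration: 20.0}
  p3_voltages: [-110.0, -100.0, -90.0, -80.0, -70.0, -60.0, -50.0,
                -40.0, -30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 40.0]
  p3_duration: 500.0
  final: {voltage: -80.0, duration: 480.0}

pr5:
  holding: {voltage: -80.0, duration: 1000.0}
  p1: {voltage: 40.0, duration: 2000.0}
  p2_voltages: [-120.0, -110.0, -100.0, -90.0, -80.0, -70.0, -60.0, -50.0,
                40.0]
  p2_duration: 6500.0
  final: {voltage: -80.0, duration: 800.0}

pr7:
  holding: {voltage: -80.0, duration: 250.0}
  step: {voltage: 40.0, duration: 750.0}
  sines:
    # Offset plus three summed sine components spanning slow (~1 Hz),
    # medium (~6 Hz) and fast (~30 Hz) timescales so that all four
    # transition rates are excited.  Angular frequencies in rad/ms.
    offset: -30.0
    duration: 6500.0
    components:
      - {amplitude: 54.0, omega: 0.007, phase: 0.0}
      - {amplitude: 26.0, omega: 0.037, phase: 0.0}
      - {amplitude: 10.0, omega: 0.190, phase: 0.0}
  final: {voltage: -80.0, duration: 500.0}
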