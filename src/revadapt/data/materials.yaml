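# Surface and air absorption tables used by the room simulator.
#
# Octave-band energy absorption coefficients (125 Hz - 4 kHz published
# range, extended flat to the band edges).  "stone" is a hard stone /
# masonry surface.  Published tables for stone-like surfaces span roughly
# 0.01-0.05; this simulator has no head-related transfer function, so the
# level within that range was fixed once so that the three study rooms
# reproduce their stated reverberation times (RT60 = 0.78 s, 1.5 s and
# 2.6 s for the small, medium and large rooms).
band_centers_hz: [125, 250, 500, 1000, 2000, 4000, 8000, 16000]
materials:
  stone:
    absorption: [0.03, 0.03, 0.03, 0.03, 0.03, 0.03, 0.03, 0.03]
# Atmospheric attenuation in dB per metre (approx. 20 degC, 50% relative
# humidity, sea-level pressure); this supplies most of the decline of
# reverberation time with frequency.
air:
  db_per_m: [0.0004, 0.0010, 0.0019, 0.0037, 0.0093, 0.0290, 0.1040, 0.3670]
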