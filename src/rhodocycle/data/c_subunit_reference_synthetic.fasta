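>c_subunit_ref_synthetic synthetic ATP-synthase c-subunit reference; Na+ quartet Q27/E60/S61/T62, H+ carboxylate E60
MESVISDLILAASAIGAGIAMIAGIGQAIGTVFGSLIIGYARNPSLKPQLFTYAILGFAE
STGIYSLVIALILLYANPFA
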