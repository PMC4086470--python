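name,youngs_modulus_pa,density_kg_m3
Pars flaccida,3.20e7,1.20e3
Pars tensa,1.00e7,1.20e3
Malleus head,1.41e10,2.55e3
Malleus neck,1.41e10,4.53e3
Malleus handle,1.41e10,3.70e3
Incus body,1.41e10,2.36e3
Incus short process,1.41e10,2.26e3
Incus long process,1.41e10,5.08e3
Stapes,1.41e10,2.20e3
Incudomalleolar joint,1.41e10,2.39e3
Incudostapedial joint,4.00e6,1.20e3
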