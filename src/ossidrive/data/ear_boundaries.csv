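name,youngs_modulus_pa,density_kg_m3
Tympanic annulus ligament,4.00e5,1.20e3
Superior mallear ligament,4.90e6,1.20e3
Lateral mallear ligament,6.70e6,1.20e3
Anterior mallear ligament,2.10e7,1.20e3
Superior incudal ligament,4.90e6,1.20e3
Posterior incudal ligament,6.50e6,1.20e3
Stapedial annulus ligament,4.10e5,1.20e3
Tensor tympani tendon,2.60e6,1.20e3
Stapedial tendon,5.20e5,1.20e3
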