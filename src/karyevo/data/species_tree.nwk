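((((Saccharomyces_cerevisiae,Saccharomyces_bayanus)Scer_Sbay,Candida_glabrata)Sacch_Cgla,Vanderwaltozyma_polyspora)WGD,(Zygosaccharomyces_rouxii,((Kluyveromyces_lactis,Ashbya_gossypii)Klac_Agos,(Lachancea_kluyveri,(Lachancea_thermotolerans,Lachancea_waltii)Lthe_Lwal)Lachancea)KLE)nonWGD)B;
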