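<?xml version='1.0' encoding='UTF-8'?>
<series name='Test series'>
<slice filename='sampleID_s002.png' nr='2' width='24723' height='18561'
anchoring='ox = 312.2&amp;oy = 533.8&amp;oz = 218.4&amp;ux = -185.7&amp;uy = -35.5&amp;uz = 6.6&amp;vx = -4.6&amp;vy = -7.5&amp;vz = -171.4'/>
<slice filename='sampleID_s008.png' nr='8' width='24722' height='17507'
anchoring='ox = 334.82142136461607&amp;oy = 485.7990978550188&amp;oz = 251.62087421842926&amp;ux = -228.65532680537657&amp;uy = -13.31692466388239&amp;uz = -11.98107468791568&amp;vx = 11.021383786310935&amp;vy = -7.154108506786784&amp;vz = -202.38817266644594'/>
</series>
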