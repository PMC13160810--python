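id,dimension,label
A1,functional,Minimalist emergency call
A2,functional,Basic vital signs monitoring
A3,functional,Clear guidance system
A4,functional,Barrier-free and safe space
A5,functional,Identity recognition and intelligent early warning
B1,appearance,Eye-catching visual design
B2,appearance,Safe and comfortable materials
B3,appearance,Integrated functional layout
B4,appearance,Elder-friendly user interface
C1,culture_management,Personalized health services
C2,culture_management,Community health platform integration
C3,culture_management,Environmental adaptation design
C4,culture_management,Easy to maintain and manage
C5,culture_management,Promote community sharing and belonging
D1,technical,System intelligent integration
D2,technical,Reliability and stability
D3,technical,Information visualization and minimalist operations
D4,technical,Modularity and scalability
D5,technical,Strict data privacy and security
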